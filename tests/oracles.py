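"""Independent brute-force oracles used by the unit and acceptance tests."""

import itertools

import numpy as np

from splitgene.seqdata import Alignment
from splitgene.trees import PhyloTree


def exhaustive_log_likelihood(tree: PhyloTree, aln: Alignment, model) -> float:
    """Sum over all internal-state assignments, column by column.

    Completely independent of the pruning implementation: transition
    matrices are taken from the model, everything else is explicit
    enumeration.  Only feasible for trees with <= 3 internal nodes.
    """
    enc = aln.encoded()
    idx = {n: i for i, n in enumerate(aln.ids())}
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    P = {id(n): model.transition_matrix(n.length)
         for n in nodes if n.parent is not None}
    total = 0.0
    for col in range(aln.n_cols):
        site = 0.0
        for assign in itertools.product(range(20), repeat=len(internals)):
            amap = {id(n): s for n, s in zip(internals, assign)}
            prob = model.pi[amap[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                parent_state = amap[id(n.parent)]
                if n.is_leaf:
                    st = int(enc[idx[n.name], col])
                    if st != 20:
                        prob *= P[id(n)][parent_state, st]
                else:
                    prob *= P[id(n)][parent_state, amap[id(n)]]
            site += prob
        total += np.log(site)
    return float(total)


def all_unrooted_topologies(names):
    """Every unrooted topology on the given leaves (1, 3 or 15 for n=3..5),
    as trees with a trifurcating root; built by stepwise addition."""
    from splitgene.trees import PhyloTree, TreeNode

    def clone(tree):
        return tree.copy()

    base = TreeNode()
    for n in names[:3]:
        base.add_child(TreeNode(n))
    trees = [PhyloTree(base)]
    for name in names[3:]:
        nxt = []
        for tree in trees:
            edges = [n for n in tree.postorder() if n.parent is not None]
            for k in range(len(edges)):
                t2 = clone(tree)
                edges2 = [n for n in t2.postorder() if n.parent is not None]
                edge = edges2[k]
                parent = edge.parent
                mid = TreeNode()
                parent.remove_child(edge)
                parent.add_child(mid)
                mid.add_child(edge)
                mid.add_child(TreeNode(name))
                nxt.append(t2)
        trees = nxt
    return trees
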