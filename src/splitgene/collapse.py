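"""Test #1: collapse weakly supported branches, look for sister fragments.

Fragments of one gene share no columns, so nothing separates them but
sampling noise; the internal branches between them should be poorly
supported.  Collapsing every internal branch whose support falls strictly
below the threshold therefore merges their attachment points, and the pair
is called split when the two fragments end up as children of the same
(possibly multifurcating) node.  The tree is treated as unrooted: an
artificial degree-2 root is contracted first, and missing supports default
to 1.0 (never collapsed).
"""

from __future__ import annotations

from dataclasses import dataclass

from .candidates import CandidatePair
from .trees import PhyloTree


@dataclass
class CollapseResult:
    pair: CandidatePair
    threshold: float
    collapsed_tree: PhyloTree
    is_split: bool
    n_collapsed: int


def collapse_low_support(tree: PhyloTree, threshold: float
                         ) -> tuple[PhyloTree, int]:
    """Contract internal branches with support < threshold (strict).

    Leaf branches are never contracted.  Returns the (possibly
    multifurcating) collapsed tree and the number of contracted branches.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    out = tree.copy()
    out.suppress_root_bifurcation()
    n_collapsed = 0
    # bottom-up so that child contractions do not disturb pending parents
    for node in list(out.postorder()):
        if node.is_leaf or node.parent is None:
            continue
        support = 1.0 if node.support is None else node.support
        if support < threshold:
            parent = node.parent
            pos = parent.children.index(node)
            parent.remove_child(node)
            for i, c in enumerate(list(node.children)):
                node.remove_child(c)
                parent.children.insert(pos + i, c)
                c.parent = parent
            n_collapsed += 1
    return out, n_collapsed


def are_sister_leaves(tree: PhyloTree, id1: str, id2: str) -> bool:
    """True iff both leaves hang off the same node (polytomies included).

    Evaluated on the unrooted tree: a degree-2 root is contracted before
    testing, so the root counts as an ordinary vertex.
    """
    work = tree.copy()
    work.suppress_root_bifurcation()
    leaf1 = work.find_leaf(id1)
    leaf2 = work.find_leaf(id2)
    return leaf1.parent is leaf2.parent and leaf1.parent is not None


def collapse_test(tree: PhyloTree, pair: CandidatePair, threshold: float
                  ) -> CollapseResult:
    """Collapse weak branches, then ask whether the pair became sisters."""
    for rid in (pair.id1, pair.id2):
        tree.find_leaf(rid)  # raises KeyError if absent
    collapsed, n = collapse_low_support(tree, threshold)
    return CollapseResult(
        pair=pair, threshold=threshold, collapsed_tree=collapsed,
        is_split=are_sister_leaves(collapsed, pair.id1, pair.id2),
        n_collapsed=n)
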