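import numpy as np
import pytest

from splitgene.seqdata import AA_ORDER, Alignment
from splitgene.substmodels import load_lg, poisson_model
from splitgene.trees import PhyloTree, TreeNode


@pytest.fixture(scope="session")
def lg():
    return load_lg()


@pytest.fixture(scope="session")
def poisson():
    return poisson_model()


def random_alignment(rng: np.random.Generator, ids, n_cols,
                     gap_frac=0.2) -> Alignment:
    """Random gapped alignment (guaranteed no all-gap columns)."""
    ids = list(ids)
    chars = rng.choice(list(AA_ORDER), size=(len(ids), n_cols))
    gaps = rng.random((len(ids), n_cols)) < gap_frac
    # keep at least one residue per column (no all-gap columns) and per row
    for j in np.nonzero(gaps.all(axis=0))[0]:
        gaps[rng.integers(0, len(ids)), j] = False
    for i in np.nonzero(gaps.all(axis=1))[0]:
        gaps[i, rng.integers(0, n_cols)] = False
    rows = {rid: "".join("-" if g else c for c, g in zip(chars[i], gaps[i]))
            for i, rid in enumerate(ids)}
    return Alignment(rows)


def random_topology(rng: np.random.Generator, names) -> PhyloTree:
    """Random unrooted topology by sequential random attachment."""
    names = list(names)
    assert len(names) >= 3
    root = TreeNode()
    for n in names[:3]:
        root.add_child(TreeNode(n, length=float(rng.uniform(0.05, 0.5))))
    edges = list(root.children)
    for name in names[3:]:
        edge = edges[rng.integers(0, len(edges))]
        parent = edge.parent
        mid = TreeNode(length=float(rng.uniform(0.05, 0.5)))
        parent.remove_child(edge)
        parent.add_child(mid)
        mid.add_child(edge)
        leaf = TreeNode(name, length=float(rng.uniform(0.05, 0.5)))
        mid.add_child(leaf)
        edge.length = float(rng.uniform(0.05, 0.5))
        edges.extend([mid, leaf])
    return PhyloTree(root)


def with_random_supports(tree: PhyloTree, rng: np.random.Generator) -> PhyloTree:
    for node in tree.postorder():
        if not node.is_leaf and node.parent is not None:
            node.support = float(rng.random())
    return tree
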