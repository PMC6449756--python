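"""Maximum-likelihood tree search: NJ start, NNI hill climbing, bootstrap.

``build_tree`` produces an unrooted ML tree (stored with a trifurcating
root): neighbor joining on pairwise ML distances gives the start, then
nearest-neighbor interchanges are accepted while they improve the
log-likelihood, with branch lengths re-optimized after every accepted move.
``bootstrap_supports`` attaches classical Felsenstein bootstrap proportions:
the fraction of column-resampled replicates whose re-estimated tree contains
the same bipartition.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .likelihood import (DEFAULT_BL, MAX_BL, MIN_BL, EngineFit, PatternData,
                         TreeLikelihood, compress_alignment)
from .seqdata import MISSING, Alignment
from .substmodels import SubstModel
from .trees import PhyloTree, TreeNode, parse_newick

#: Pairs sharing fewer informative columns than this get an imputed distance.
MIN_SHARED_COLUMNS = 10


# ---- pairwise ML distances ----------------------------------------------

def _pair_counts(row_i: np.ndarray, row_j: np.ndarray, weights: np.ndarray
                 ) -> np.ndarray:
    mask = (row_i != MISSING) & (row_j != MISSING)
    if not mask.any():
        return np.zeros((20, 20))
    code = row_i[mask].astype(int) * 20 + row_j[mask].astype(int)
    N = np.bincount(code, weights=weights[mask], minlength=400)
    return N.reshape(20, 20)


def _count_ll(N: np.ndarray, model: SubstModel, t: float) -> float:
    Ps = np.stack([model.transition_matrix(t, r) for r in model.rates])
    site = np.mean(model.pi[None, :, None] * Ps, axis=0)
    with np.errstate(divide="ignore"):
        return float((N * np.log(site)).sum())


def ml_pairwise_distance(N: np.ndarray, model: SubstModel) -> float:
    """Distance maximizing the two-sequence likelihood from a count matrix."""
    res = minimize_scalar(lambda t: -_count_ll(N, model, t),
                          bounds=(MIN_BL, MAX_BL), method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


def ml_distance_matrix(data: PatternData, model: SubstModel,
                       weights: np.ndarray | None = None) -> np.ndarray:
    """Pairwise ML distances; near-disjoint pairs (fragments) are imputed
    by the smallest through-a-third-taxon path bound min_k(d_ik + d_jk)."""
    w = data.weights if weights is None else weights
    n = len(data.names)
    D = np.zeros((n, n))
    shared = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            N = _pair_counts(data.matrix[i], data.matrix[j], w)
            shared[i, j] = shared[j, i] = N.sum()
            if N.sum() >= MIN_SHARED_COLUMNS:
                D[i, j] = D[j, i] = ml_pairwise_distance(N, model)
            else:
                D[i, j] = D[j, i] = np.nan
    # impute undefined distances through the best shared third taxon
    for i in range(n):
        for j in range(i + 1, n):
            if np.isnan(D[i, j]):
                candidates = [D[i, k] + D[k, j] for k in range(n)
                              if k not in (i, j)
                              and not (np.isnan(D[i, k]) or np.isnan(D[k, j]))]
                D[i, j] = D[j, i] = min(candidates) if candidates else 1.0
    return D


def nj_tree(D: np.ndarray, names: list[str]) -> PhyloTree:
    """Neighbor joining (via scikit-bio) on a distance matrix."""
    from skbio import DistanceMatrix
    from skbio.tree import nj
    sym = 0.5 * (D + D.T)
    np.fill_diagonal(sym, 0.0)
    sk = nj(DistanceMatrix(sym, ids=names))
    tree = parse_newick(str(sk))
    tree.suppress_root_bifurcation()
    for node in tree.postorder():
        if node.parent is not None:
            if node.length is None or not np.isfinite(node.length):
                node.length = DEFAULT_BL
            node.length = min(max(node.length, MIN_BL), MAX_BL)
    return tree


# ---- NNI search ----------------------------------------------------------

def _nni_edges(tree: PhyloTree) -> list[TreeNode]:
    """Internal edges eligible for NNI, identified by their child node."""
    return [n for n in tree.postorder()
            if not n.is_leaf and n.parent is not None and len(n.children) == 2]


def _swap(c: TreeNode, x: TreeNode, s: TreeNode) -> None:
    """Exchange subtree x (child of c) with subtree s (child of c's parent)."""
    p = c.parent
    c.remove_child(x)
    p.remove_child(s)
    c.add_child(s)
    p.add_child(x)


def _nni_candidates(c: TreeNode):
    p = c.parent
    s = next(ch for ch in p.children if ch is not c)
    x, y = c.children
    return [(x, s), (y, s)]


def build_tree(msa: Alignment, model: SubstModel,
               start: PhyloTree | None = None, seed: int = 0,
               tol: float = 1e-4, nni: bool = True, max_sweeps: int = 10,
               xatol: float = 1e-5, data: PatternData | None = None
               ) -> EngineFit:
    """ML tree search (NJ + NNI de novo, or NNI from a given start tree)."""
    if data is None:
        data = compress_alignment(msa)
    if len(data.names) < 2:
        raise ValueError("tree search needs at least 2 sequences")
    if start is None:
        if len(data.names) == 2:
            a, b = data.names
            root = TreeNode()
            root.add_child(TreeNode(a, DEFAULT_BL))
            root.add_child(TreeNode(b, DEFAULT_BL))
            tree = PhyloTree(root)
        else:
            D = ml_distance_matrix(data, model)
            tree = nj_tree(D, data.names)
    else:
        tree = start.copy()
        tree.suppress_root_bifurcation()
        for node in tree.postorder():
            if node.parent is not None and node.length is None:
                node.length = DEFAULT_BL
            node.support = None
    tl = TreeLikelihood(tree, data, model)
    fit = tl.optimize_branch_lengths(tol=tol, xatol=xatol)
    if not nni or len(data.names) <= 3:
        return fit
    current = fit.log_likelihood
    for _ in range(max_sweeps):
        improved = False
        for c in _nni_edges(tree):
            if c.parent is None or len(c.children) != 2:
                continue  # a previous accepted move restructured this edge
            best = (current, None)
            for x, s in _nni_candidates(c):
                _swap(c, x, s)
                tl.invalidate()
                ll = tl.optimize_single_edge(c, xatol=max(xatol, 1e-3))
                if ll > best[0]:
                    best = (ll, (x, s))
                _swap(c, s, x)  # revert
            tl.invalidate()
            if best[1] is not None and best[0] > current + tol:
                x, s = best[1]
                _swap(c, x, s)
                tl.invalidate()
                current = tl.optimize_branch_lengths(
                    tol=tol, xatol=xatol).log_likelihood
                improved = True
        if not improved:
            break
    tl.invalidate()
    final = tl.optimize_branch_lengths(tol=tol, xatol=xatol)
    return final


# ---- bootstrap supports --------------------------------------------------

def bootstrap_supports(msa: Alignment, model: SubstModel, tree: PhyloTree,
                       n_reps: int = 100, seed: int = 0,
                       rebuild: str = "nj") -> PhyloTree:
    """Felsenstein bootstrap proportions on the internal branches of ``tree``.

    Columns are resampled with replacement; each replicate tree is re-built
    (``rebuild="nj"``: NJ on re-estimated ML distances, the classical
    distance bootstrap; ``rebuild="full"``: complete NJ+NNI search) and a
    branch's support is the fraction of replicates containing its
    bipartition.  Replicate r uses seed + r.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rebuild not in ("nj", "full"):
        raise ValueError(f"unknown rebuild mode {rebuild!r}")
    data = compress_alignment(msa)
    enc = msa.encoded()
    _, inverse = np.unique(enc, axis=1, return_inverse=True)
    counts: dict[frozenset, int] = {}
    for r in range(1, n_reps + 1):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        w = np.bincount(inverse[cols], minlength=data.matrix.shape[1]
                        ).astype(float)
        if rebuild == "nj":
            D = ml_distance_matrix(data, model, weights=w)
            rep_tree = nj_tree(D, data.names)
        else:
            rep_aln = Alignment({rid: "".join(msa.rows[rid][j] for j in cols)
                                 for rid in msa.ids()})
            rep_tree = build_tree(rep_aln, model, seed=seed + r).tree
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    out = tree.copy()
    out.suppress_root_bifurcation()
    all_leaves = frozenset(out.leaf_names())
    anchor = min(all_leaves)
    below: dict[int, frozenset] = {}
    for node in out.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
            continue
        clade = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = clade
        if node.parent is None:
            continue
        side = clade if anchor not in clade else all_leaves - clade
        if 1 < len(side) < len(all_leaves) - 1:
            node.support = counts.get(side, 0) / n_reps
    return out
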