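"""Test #2: likelihood ratio test of one-gene vs two-paralogs hypotheses.

The null hypothesis H_s says the two candidate fragments are pieces of one
gene, so their rows are merged into a single sequence and the family has
n - 1 genes; the alternative H_p keeps them as two paralogous genes.  The
statistic is T = 2 ln[L(H_p)/L(H_s)] with L() the maximized likelihood
under each hypothesis.  Because the hypotheses are not nested, the null
distribution is estimated by a non-parametric bootstrap: columns of the
merged (H_s) alignment are resampled with replacement, each replicate is
split back into two fragments at the same positions (tracked per column, so
duplicated or omitted columns are handled exactly), and the statistic is
recomputed, giving T*_1..n.  The empirical p-value is
p_B = #{T*_i >= T_0}/n, and *failure to reject* the null (p_B >= alpha)
yields the split-gene prediction.

To guard against a suboptimal H_p search reporting T_0 < 0, two searches are
run under H_p: a de-novo search, and a search started from the H_s tree with
the merged leaf expanded into a (fragment1, fragment2) cherry; the better
likelihood is used.  With gaps as missing data the zero-length cherry
reproduces the H_s likelihood, so T_0 >= -2*tol by construction.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

from .candidates import CandidatePair, aligned_overlap, passes_overlap_filter
from .likelihood import EngineFit, TreeLikelihood, compress_alignment
from .seqdata import GAP, Alignment
from .substmodels import SubstModel
from .trees import PhyloTree, TreeNode
from .treesearch import build_tree

# per-column provenance codes
NONE, F1, F2, BOTH = 0, 1, 2, 3
_CHERRY_PENDANT = 1e-6


@dataclass
class MergedAlignment:
    """Family alignment with the candidate pair merged into one row.

    ``id1`` is the fragment with more residues (ties broken towards the
    lexicographically smaller id); at the rare columns where both fragments
    hold a residue (allowed below the 10% overlap cap) the merged row takes
    ``id1``'s residue and the column is labelled BOTH.
    """

    alignment: Alignment
    merged_id: str
    id1: str
    id2: str
    provenance: np.ndarray  # (n_cols,) int8 with NONE/F1/F2/BOTH codes


@dataclass
class LrtResult:
    pair: CandidatePair
    T0: float
    replicates: list[float]
    p_B: float
    alpha: float
    is_split: bool
    n_boot: int
    mode: str
    seed: int
    fit_s: EngineFit | None = None
    fit_p: EngineFit | None = None


def merge_fragments(msa: Alignment, ida: str, idb: str,
                    max_frac: float = 0.1) -> MergedAlignment:
    """Concatenate the two fragment rows into one merged row."""
    stats = aligned_overlap(msa, ida, idb)
    if not passes_overlap_filter(stats, max_frac):
        raise ValueError(
            f"pair ({ida}, {idb}) fails the overlap filter: {stats}")
    la = len(msa.ungapped(ida))
    lb = len(msa.ungapped(idb))
    # the longer fragment donates overlap residues; ties: smaller id
    if la > lb or (la == lb and ida < idb):
        id1, id2 = ida, idb
    else:
        id1, id2 = idb, ida
    row1, row2 = msa.rows[id1], msa.rows[id2]
    merged_chars = []
    prov = np.zeros(msa.n_cols, dtype=np.int8)
    for j in range(msa.n_cols):
        c1, c2 = row1[j], row2[j]
        if c1 != GAP and c2 != GAP:
            prov[j] = BOTH
            merged_chars.append(c1)
        elif c1 != GAP:
            prov[j] = F1
            merged_chars.append(c1)
        elif c2 != GAP:
            prov[j] = F2
            merged_chars.append(c2)
        else:
            merged_chars.append(GAP)
    merged_id = f"{id1}+{id2}"
    aln = msa.replace_row(id1, merged_id, "".join(merged_chars)).drop_row(id2)
    return MergedAlignment(alignment=aln, merged_id=merged_id,
                           id1=id1, id2=id2, provenance=prov)


def split_merged(merged: MergedAlignment) -> Alignment:
    """Inverse of the merge: route each column by its provenance label.

    ``id1`` receives the residues at F1 and BOTH columns, ``id2`` those at F2
    columns (its residues at BOTH columns were dropped by the merge - a
    documented lossy corner of partially overlapping pairs).
    """
    mrow = merged.alignment.rows[merged.merged_id]
    prov = merged.provenance
    row1 = "".join(mrow[j] if prov[j] in (F1, BOTH) else GAP
                   for j in range(len(mrow)))
    row2 = "".join(mrow[j] if prov[j] == F2 else GAP
                   for j in range(len(mrow)))
    rows: "OrderedDict[str, str]" = OrderedDict()
    for rid, row in merged.alignment.rows.items():
        if rid == merged.merged_id:
            rows[merged.id1] = row1
            rows[merged.id2] = row2
        else:
            rows[rid] = row
    return Alignment(rows)


def resample_merged(merged: MergedAlignment, rng: np.random.Generator
                    ) -> MergedAlignment:
    """Bootstrap replicate: columns drawn with replacement, labels carried."""
    n = merged.alignment.n_cols
    cols = rng.integers(0, n, size=n)
    rows = OrderedDict(
        (rid, "".join(row[j] for j in cols))
        for rid, row in merged.alignment.rows.items())
    return MergedAlignment(alignment=Alignment(rows),
                           merged_id=merged.merged_id,
                           id1=merged.id1, id2=merged.id2,
                           provenance=merged.provenance[cols])


def cherry_start_tree(hs_tree: PhyloTree, merged_id: str, id1: str, id2: str
                      ) -> PhyloTree:
    """H_s tree with the merged leaf expanded into an (id1, id2) cherry.

    The stem keeps its optimized length; the two new pendant branches start
    near zero, which reproduces the H_s likelihood before re-optimization.
    """
    tree = hs_tree.copy()
    leaf = tree.find_leaf(merged_id)
    leaf.name = None
    leaf.add_child(TreeNode(id1, _CHERRY_PENDANT))
    leaf.add_child(TreeNode(id2, _CHERRY_PENDANT))
    return tree


@dataclass
class LrtFits:
    fit_s: EngineFit
    fit_p_denovo: EngineFit
    fit_p_guided: EngineFit

    @property
    def fit_p(self) -> EngineFit:
        return max((self.fit_p_denovo, self.fit_p_guided),
                   key=lambda f: f.log_likelihood)


def lrt_statistic(msa: Alignment, pair: CandidatePair, model: SubstModel,
                  seed: int = 0, max_frac: float = 0.1, tol: float = 1e-4,
                  merged: MergedAlignment | None = None
                  ) -> tuple[float, LrtFits, MergedAlignment]:
    """T_0 = 2*[lnL(H_p) - lnL(H_s)] with the dual H_p search."""
    if merged is None:
        merged = merge_fragments(msa, pair.id1, pair.id2, max_frac=max_frac)
    fit_s = build_tree(merged.alignment, model, seed=seed, tol=tol)
    fit_p1 = build_tree(msa, model, seed=seed, tol=tol)
    start = cherry_start_tree(fit_s.tree, merged.merged_id,
                              merged.id1, merged.id2)
    fit_p2 = build_tree(msa, model, start=start, seed=seed, tol=tol)
    fits = LrtFits(fit_s=fit_s, fit_p_denovo=fit_p1, fit_p_guided=fit_p2)
    T0 = 2.0 * (fits.fit_p.log_likelihood - fit_s.log_likelihood)
    return T0, fits, merged


#: Convergence settings for per-replicate branch-length refits ("fast"
#: mode): replicate statistics are only compared against T0, so a coarser
#: log-likelihood tolerance than the final fits' 1e-4 is ample.
FAST_REFIT_TOL = 0.05
FAST_REFIT_XATOL = 2e-3
FAST_REFIT_ROUNDS = 3


def _fast_refit(tree: PhyloTree, aln: Alignment, model: SubstModel) -> float:
    work = tree.copy()
    tl = TreeLikelihood(work, compress_alignment(aln), model)
    return tl.optimize_branch_lengths(tol=FAST_REFIT_TOL,
                                      xatol=FAST_REFIT_XATOL,
                                      max_rounds=FAST_REFIT_ROUNDS,
                                      warm=True).log_likelihood


def bootstrap_null(merged: MergedAlignment, model: SubstModel,
                   n: int = 100, seed: int = 0, mode: str = "full",
                   fits: LrtFits | None = None, tol: float = 1e-4
                   ) -> list[float]:
    """Replicate statistics T*_1..n from column resampling of H_s data.

    mode "full": topology re-searched per replicate, mirroring the original
    statistic (H_s on the resampled merged alignment; H_p as the better of a
    de-novo and a cherry-guided search on its provenance-split counterpart).
    mode "fast": both topologies are frozen at the original fits and only
    branch lengths are re-optimized per replicate.  Replicate r derives its
    seed as seed + r.
    """
    if n < 1:
        raise ValueError("bootstrap needs n >= 1 replicates")
    if mode not in ("full", "fast"):
        raise ValueError(f"unknown replicate mode {mode!r}")
    if mode == "fast" and fits is None:
        raise ValueError("fast mode needs the original fits")
    out: list[float] = []
    for r in range(1, n + 1):
        rng = np.random.default_rng(seed + r)
        rep = resample_merged(merged, rng)
        rep_split = split_merged(rep)
        if mode == "fast":
            lnl_s = _fast_refit(fits.fit_s.tree, rep.alignment, model)
            lnl_p = _fast_refit(fits.fit_p.tree, rep_split, model)
            out.append(2.0 * (lnl_p - lnl_s))
        else:
            fit_s = build_tree(rep.alignment, model, seed=seed + r, tol=tol)
            fit_p1 = build_tree(rep_split, model, seed=seed + r, tol=tol)
            start = cherry_start_tree(fit_s.tree, rep.merged_id,
                                      rep.id1, rep.id2)
            fit_p2 = build_tree(rep_split, model, start=start,
                                seed=seed + r, tol=tol)
            lnl_p = max(fit_p1.log_likelihood, fit_p2.log_likelihood)
            out.append(2.0 * (lnl_p - fit_s.log_likelihood))
    return out


def bootstrap_pvalue(T0: float, Ts: list[float]) -> float:
    """p_B = #{T*_i >= T0} / n; ties count towards the numerator."""
    if not Ts:
        raise ValueError("empty replicate list")
    count = sum(1 for t in Ts if t >= T0)
    return count / len(Ts)


def lrt_test(msa: Alignment, pair: CandidatePair, model: SubstModel,
             alpha: float = 0.01, n: int = 100, seed: int = 0,
             mode: str = "full", max_frac: float = 0.1, tol: float = 1e-4
             ) -> LrtResult:
    """Full LRT: the pair is called split when p_B >= alpha.

    Failing to reject the one-gene null is what licenses the prediction, so
    large p-values - including those from a negative T0 - lead to a split
    call.
    """
    T0, fits, merged = lrt_statistic(msa, pair, model, seed=seed,
                                     max_frac=max_frac, tol=tol)
    Ts = bootstrap_null(merged, model, n=n, seed=seed, mode=mode,
                        fits=fits, tol=tol)
    p = bootstrap_pvalue(T0, Ts)
    return LrtResult(pair=pair, T0=T0, replicates=Ts, p_B=p, alpha=alpha,
                     is_split=(p >= alpha), n_boot=n, mode=mode, seed=seed,
                     fit_s=fits.fit_s, fit_p=fits.fit_p)
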