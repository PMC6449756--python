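"""Built-in progressive multiple aligner (fallback when no external tool).

A deliberately small profile aligner: a guide tree from average-linkage
clustering of 3-mer profile distances, then profile-profile Needleman-Wunsch
with BLOSUM62 expected scores and a linear gap penalty.  It is adequate for
the moderately diverged protein families this package analyses; for
production data an external aligner adapter (e.g. MAFFT) is preferable.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .seqdata import AA_INDEX, AA_ORDER, GAP, Alignment, ProteinSequence

GAP_PENALTY = -4.0
_GAP_STATE = 20  # index of the gap state in profile frequency vectors


def _score_matrix() -> np.ndarray:
    """21x21 expected-score matrix over (20 aa + gap) from BLOSUM62."""
    blosum = substitution_matrices.load("BLOSUM62")
    S = np.zeros((21, 21))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            S[i, j] = blosum[a][b]
    S[_GAP_STATE, :20] = GAP_PENALTY
    S[:20, _GAP_STATE] = GAP_PENALTY
    S[_GAP_STATE, _GAP_STATE] = 0.0
    return S


_S = _score_matrix()


def _kmer_profile(seq: str, k: int = 3) -> np.ndarray:
    prof = np.zeros(20 ** k)
    idx = [AA_INDEX.get(c) for c in seq]
    for i in range(len(seq) - k + 1):
        window = idx[i:i + k]
        if None in window:
            continue
        code = 0
        for v in window:
            code = code * 20 + v
        prof[code] += 1.0
    n = prof.sum()
    return prof / n if n else prof


def _profile(rows: "OrderedDict[str, str]") -> np.ndarray:
    """(n_cols, 21) frequency profile; X counts as gap (uninformative)."""
    n_cols = len(next(iter(rows.values())))
    F = np.zeros((n_cols, 21))
    for row in rows.values():
        for j, ch in enumerate(row):
            F[j, AA_INDEX.get(ch, _GAP_STATE)] += 1.0
    return F / len(rows)


def _align_profiles(rows_a: "OrderedDict[str, str]",
                    rows_b: "OrderedDict[str, str]") -> "OrderedDict[str, str]":
    Fa = _profile(rows_a)
    Fb = _profile(rows_b)
    la, lb = len(Fa), len(Fb)
    sub = Fa @ _S @ Fb.T                       # (la, lb) column match scores
    gap_a = GAP_PENALTY * (1.0 - Fa[:, _GAP_STATE])   # gap inserted in B
    gap_b = GAP_PENALTY * (1.0 - Fb[:, _GAP_STATE])   # gap inserted in A
    M = np.empty((la + 1, lb + 1))
    M[0, :] = np.concatenate([[0.0], np.cumsum(gap_b)])
    M[:, 0] = np.concatenate([[0.0], np.cumsum(gap_a)])
    cum_b = M[0, :]
    for i in range(1, la + 1):
        diag = M[i - 1, :-1] + sub[i - 1]
        up = M[i - 1, 1:] + gap_a[i - 1]
        C = np.maximum(diag, up)
        # running max for the left-gap recurrence with a linear penalty
        shifted = np.concatenate([[M[i, 0]], C]) - cum_b
        M[i, 1:] = np.maximum.accumulate(shifted)[1:] + cum_b[1:]
    # traceback
    i, j = la, lb
    path: list[tuple[bool, bool]] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(M[i, j], M[i - 1, j - 1] + sub[i - 1, j - 1]):
            path.append((True, True)); i -= 1; j -= 1
        elif i > 0 and np.isclose(M[i, j], M[i - 1, j] + gap_a[i - 1]):
            path.append((True, False)); i -= 1
        elif j > 0:
            path.append((False, True)); j -= 1
        else:
            path.append((True, False)); i -= 1
    path.reverse()
    out: "OrderedDict[str, str]" = OrderedDict()
    for rid, row in rows_a.items():
        chars, k = [], 0
        for use_a, _ in path:
            chars.append(row[k] if use_a else GAP)
            k += use_a
        out[rid] = "".join(chars)
    for rid, row in rows_b.items():
        chars, k = [], 0
        for _, use_b in path:
            chars.append(row[k] if use_b else GAP)
            k += use_b
        out[rid] = "".join(chars)
    return out


def progressive_align(seqs: Sequence[ProteinSequence]) -> Alignment:
    """Align sequences progressively along a 3-mer-distance guide tree."""
    if not seqs:
        raise ValueError("nothing to align")
    if len(seqs) == 1:
        return Alignment({seqs[0].id: seqs[0].residues})
    profiles = np.array([_kmer_profile(s.residues) for s in seqs])
    dists = pdist(profiles, metric="cosine")
    dists = np.nan_to_num(dists, nan=1.0)
    Z = linkage(dists, method="average")
    groups: dict[int, "OrderedDict[str, str]"] = {
        i: OrderedDict({s.id: s.residues}) for i, s in enumerate(seqs)}
    n = len(seqs)
    for step, (a, b, _, _) in enumerate(Z):
        merged = _align_profiles(groups.pop(int(a)), groups.pop(int(b)))
        groups[n + step] = merged
    (rows,) = groups.values()
    # restore input order for determinism and readability
    ordered = OrderedDict((s.id, rows[s.id]) for s in seqs)
    aln = Alignment(ordered).without_allgap_columns()
    for s in seqs:
        if aln.ungapped(s.id) != s.residues:
            raise AssertionError(f"aligner corrupted sequence {s.id}")
    return aln
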