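"""Candidate split-gene pair enumeration.

Two gene models from the target genome are a candidate pair when both are at
least ``min_len`` residues long and they are (nearly) non-overlapping in the
family alignment: fewer than 10% of either fragment's residues may sit in a
column where the other fragment also holds a residue.  The inequalities are
strict, so a pair exactly at the 10% mark is rejected.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .seqdata import Alignment, GeneFamily

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapStats:
    """Aligned-overlap statistics for a pair of rows.

    l1, l2: ungapped lengths (aa); a12: number of columns where both rows
    hold a residue.  Symmetric in the two sequences.
    """

    l1: int
    l2: int
    a12: int

    def __post_init__(self):
        if not (0 <= self.a12 <= min(self.l1, self.l2)):
            raise ValueError(f"inconsistent overlap stats {self}")


@dataclass(frozen=True)
class CandidatePair:
    """Two same-family target-genome genes passing the length/overlap filters."""

    family_id: str
    id1: str
    id2: str
    stats: OverlapStats

    def __post_init__(self):
        if not self.id1 < self.id2:
            raise ValueError("candidate pair ids must be ordered id1 < id2")


def aligned_overlap(msa: Alignment, id1: str, id2: str) -> OverlapStats:
    """Count residues of the two rows aligned in the same column."""
    for rid in (id1, id2):
        if rid not in msa:
            raise KeyError(f"id {rid!r} is not a row of the alignment")
    occ1 = msa.occupancy(id1)
    occ2 = msa.occupancy(id2)
    a12 = len(np.intersect1d(occ1, occ2, assume_unique=True))
    return OverlapStats(l1=len(occ1), l2=len(occ2), a12=a12)


def passes_overlap_filter(stats: OverlapStats, max_frac: float = 0.1) -> bool:
    """Strict rule: a12 < max_frac*l1 AND a12 < max_frac*l2."""
    return stats.a12 < max_frac * stats.l1 and stats.a12 < max_frac * stats.l2


def read_location_map(path) -> dict[str, str]:
    """Optional TSV ``gene_id<TAB>location`` for the same-location gate."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, loc = line.split("\t")[:2]
            out[gene] = loc
    return out


def enumerate_candidates(family: GeneFamily, msa: Alignment,
                         min_len: int = 50, max_frac: float = 0.1,
                         location_map: Mapping[str, str] | None = None,
                         ) -> list[CandidatePair]:
    """All unordered target-genome pairs passing the length and overlap rules.

    Output is deterministic (sorted by id1, then id2).  Families with fewer
    than two target-genome genes yield an empty list.  When a location map is
    supplied, both genes must share a location (same contig / chromosome arm).
    """
    targets = sorted(s.id for s in family.target_members)
    if len(targets) < 2:
        log.info("family %s: <2 target-genome genes, no pairs", family.family_id)
        return []
    out: list[CandidatePair] = []
    for id1, id2 in itertools.combinations(targets, 2):
        if id1 not in msa or id2 not in msa:
            raise KeyError(f"family {family.family_id}: {id1}/{id2} missing from MSA")
        stats = aligned_overlap(msa, id1, id2)
        if stats.l1 < min_len or stats.l2 < min_len:
            continue
        if not passes_overlap_filter(stats, max_frac):
            continue
        if location_map is not None:
            loc1, loc2 = location_map.get(id1), location_map.get(id2)
            if loc1 is None or loc2 is None or loc1 != loc2:
                continue
        out.append(CandidatePair(family_id=family.family_id, id1=id1, id2=id2,
                                 stats=stats))
    return out
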