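"""Sequence, gene-family and alignment containers plus FASTA/TSV readers.

The pipeline analyses protein gene families: every sequence carries a genome
label, one genome per dataset is the *target* genome whose annotation is being
screened for split genes, and each family is the unit of analysis.  Amino
acids are held over the 20 canonical letters plus ``X`` for anything
ambiguous; ``X`` (and alignment gaps) are treated as missing data by the
likelihood machinery.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

#: Canonical amino-acid order used throughout (matches the PAML convention of
#: the shipped substitution-model files).
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
#: Integer code for missing data (gap or X) in encoded alignments.
MISSING = 20
GAP = "-"
# Ambiguity / rare letters folded into X (missing data downstream).
_AMBIGUOUS = set("BZUOJ")


def normalize_residues(raw: str) -> str:
    """Uppercase, strip terminal stop symbols, fold ambiguity codes to X."""
    s = raw.strip().upper().rstrip("*")
    out = []
    for ch in s:
        if ch in AA_INDEX or ch == "X":
            out.append(ch)
        elif ch in _AMBIGUOUS:
            out.append("X")
        elif ch == "*":
            # internal stop: treat as missing rather than failing the record
            out.append("X")
        else:
            raise ValueError(f"invalid amino-acid symbol {ch!r} in sequence")
    return "".join(out)


@dataclass(frozen=True)
class ProteinSequence:
    """One annotated protein with its genome of origin."""

    id: str
    residues: str
    genome: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"empty sequence for id {self.id}")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class GeneFamily:
    """A gene family: member sequences labelled by genome, one target genome."""

    family_id: str
    members: "OrderedDict[str, ProteinSequence]"
    target_genome: str

    def __len__(self) -> int:
        return len(self.members)

    @property
    def target_members(self) -> list[ProteinSequence]:
        return [s for s in self.members.values() if s.genome == self.target_genome]

    def __iter__(self):
        return iter(self.members.values())


def read_fasta(path, genome_map: Mapping[str, str] | None = None,
               default_genome: str = "") -> list[ProteinSequence]:
    """Read protein FASTA; the first header token is the id.

    A ``genome=NAME`` key in the description sets the genome label unless a
    ``genome_map`` is given, which then is the single source of truth.
    Duplicate ids and empty sequences are hard errors.
    """
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in seen:
            raise ValueError(f"duplicate id {sid} in {path}")
        seen.add(sid)
        genome = default_genome
        for tok in rec.description.split()[1:]:
            if tok.startswith("genome="):
                genome = tok[len("genome="):]
        if genome_map is not None:
            genome = genome_map.get(sid, genome)
        residues = normalize_residues(str(rec.seq))
        if not residues:
            raise ValueError(f"empty sequence for id {sid} in {path}")
        out.append(ProteinSequence(id=sid, residues=residues, genome=genome))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id}"
            if s.genome:
                header += f" genome={s.genome}"
            fh.write(header + "\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i:i + 60] + "\n")


def read_family_map(path) -> dict[str, dict[str, str]]:
    """Read a TSV ``gene_id<TAB>genome_id<TAB>family_id`` into skeletons.

    Returns ``{family_id: {gene_id: genome_id}}``.  A gene listed in two
    families is a hard error: families must partition the genes.
    """
    fams: dict[str, dict[str, str]] = {}
    gene_to_fam: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_id", "genome_id", "family_id"]:
            raise ValueError(
                f"{path}: expected header gene_id<TAB>genome_id<TAB>family_id, "
                f"got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            gene, genome, fam = parts[:3]
            if gene in gene_to_fam and gene_to_fam[gene] != fam:
                raise ValueError(
                    f"gene {gene} assigned to two families "
                    f"({gene_to_fam[gene]} and {fam})")
            gene_to_fam[gene] = fam
            fams.setdefault(fam, {})[gene] = genome
    return fams


def assemble_families(seqs: Sequence[ProteinSequence],
                      family_map: Mapping[str, Mapping[str, str]],
                      target_genome: str) -> list[GeneFamily]:
    """Join sequences with the family map; genome labels come from the map.

    Sequences absent from the map are logged and dropped; family members with
    no sequence are a hard error (the dataset is incomplete).
    """
    by_id = {s.id: s for s in seqs}
    mapped = {g for fam in family_map.values() for g in fam}
    for sid in by_id:
        if sid not in mapped:
            log.info("gene %s appears in no family; dropped", sid)
    out = []
    for fam_id in sorted(family_map):
        members: OrderedDict[str, ProteinSequence] = OrderedDict()
        for gene_id, genome in family_map[fam_id].items():
            if gene_id not in by_id:
                raise ValueError(f"family {fam_id}: no sequence for gene {gene_id}")
            s = by_id[gene_id]
            members[gene_id] = ProteinSequence(id=s.id, residues=s.residues,
                                               genome=genome)
        out.append(GeneFamily(family_id=fam_id, members=members,
                              target_genome=target_genome))
    return out


class Alignment:
    """A gapped multiple sequence alignment over a shared column axis.

    Rows are kept in insertion order.  ``occupancy(id)`` gives the column
    indices where the row holds a residue; ungapping a row must reproduce the
    member's residues exactly.
    """

    def __init__(self, rows: Mapping[str, str]):
        self.rows: "OrderedDict[str, str]" = OrderedDict(rows)
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.n_cols = lengths.pop()
        self._encoded: np.ndarray | None = None

    def ids(self) -> list[str]:
        return list(self.rows)

    def __contains__(self, rid: str) -> bool:
        return rid in self.rows

    def __len__(self) -> int:
        return len(self.rows)

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace(GAP, "")

    def occupancy(self, rid: str) -> np.ndarray:
        row = np.frombuffer(self.rows[rid].encode(), dtype=np.uint8)
        return np.nonzero(row != ord(GAP))[0]

    def encoded(self) -> np.ndarray:
        """Integer matrix (n_rows, n_cols); gaps and X coded as MISSING."""
        if self._encoded is None:
            mat = np.full((len(self.rows), self.n_cols), MISSING, dtype=np.int8)
            for i, row in enumerate(self.rows.values()):
                for j, ch in enumerate(row):
                    mat[i, j] = AA_INDEX.get(ch, MISSING)
            self._encoded = mat
        return self._encoded

    def subset(self, ids: Iterable[str]) -> "Alignment":
        return Alignment(OrderedDict((i, self.rows[i]) for i in ids))

    def without_allgap_columns(self) -> "Alignment":
        mat = np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                        for r in self.rows.values()])
        keep = np.nonzero((mat != ord(GAP)).any(axis=0))[0]
        if len(keep) == self.n_cols:
            return self
        return Alignment(OrderedDict(
            (rid, "".join(row[j] for j in keep))
            for rid, row in self.rows.items()))

    def replace_row(self, old_id: str, new_id: str, new_row: str) -> "Alignment":
        rows = OrderedDict()
        for rid, row in self.rows.items():
            if rid == old_id:
                rows[new_id] = new_row
            else:
                rows[rid] = row
        return Alignment(rows)

    def drop_row(self, rid: str) -> "Alignment":
        rows = OrderedDict((r, v) for r, v in self.rows.items() if r != rid)
        return Alignment(rows)


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA into an Alignment (residues normalized)."""
    rows: "OrderedDict[str, str]" = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate id {rec.id} in {path}")
        chars = []
        for ch in str(rec.seq).upper():
            if ch == GAP or ch == ".":
                chars.append(GAP)
            elif ch in AA_INDEX or ch == "X":
                chars.append(ch)
            elif ch in _AMBIGUOUS or ch == "*":
                chars.append("X")
            else:
                raise ValueError(f"invalid symbol {ch!r} in aligned row {rec.id}")
        rows[rec.id] = "".join(chars)
    return Alignment(rows)


def write_alignment(aln: Alignment, path) -> None:
    """Write aligned FASTA; all-gap columns are stripped first."""
    aln = aln.without_allgap_columns()
    with open(path, "w") as fh:
        for rid, row in aln.rows.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i:i + 60] + "\n")
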