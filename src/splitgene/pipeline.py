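"""Per-family orchestration, combined decision, ambiguity, reports.

For every gene family with at least four members the pipeline aligns the
sequences (precomputed alignment, external adapter, or the built-in
progressive aligner), enumerates candidate fragment pairs, runs the
configured tests, and combines them: in the default ``intersection`` mode a
split gene is predicted only when the collapse test and the LRT agree.
Genes taking part in several predictions are then screened: predictions
sharing a gene whose partner fragments overlap the same alignment region
(>= 10% by the candidate rule) cannot all be right and are labelled
``ambiguous``; compatible multi-way predictions (a gene split into more than
two pieces) stay ``unambiguous``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .aligner import progressive_align
from .adapters import ExternalTool
from .candidates import (CandidatePair, aligned_overlap, enumerate_candidates,
                         passes_overlap_filter, read_location_map)
from .collapse import CollapseResult, collapse_test
from .lrt import LrtResult, lrt_test
from .seqdata import (Alignment, GeneFamily, assemble_families, read_alignment,
                      read_family_map, read_fasta)
from .substmodels import SubstModel, get_model
from .treesearch import bootstrap_supports, build_tree

log = logging.getLogger(__name__)

UNAMBIGUOUS = "unambiguous"
AMBIGUOUS = "ambiguous"

PREDICTIONS_COLUMNS = [
    "family_id", "id1", "id2", "l1", "l2", "a12",
    "collapse_support_threshold", "collapse_is_split",
    "T0", "n_boot", "p_B", "alpha", "lrt_is_split",
    "combined_split", "ambiguity", "chain",
]


@dataclass
class RunConfig:
    """All knobs of a run; defaults follow the recommended operating point
    (collapse threshold 0.95, LRT significance 0.01)."""

    collapse_threshold: float = 0.95
    alpha: float = 0.01
    n_boot: int = 100
    min_len: int = 50
    max_overlap_frac: float = 0.1
    mode: str = "intersection"          # collapse | lrt | intersection
    model: str = "LG"
    replicate_mode: str = "full"        # full | fast (LRT bootstrap)
    support_rebuild: str = "nj"         # nj | full (bootstrap supports)
    seed: int = 0
    target_genome: str = ""
    aligner_command: str | None = None   # external aligner template, optional
    treebuilder_command: str | None = None
    location_map: str | None = None

    def __post_init__(self):
        if self.mode not in ("collapse", "lrt", "intersection"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.collapse_threshold <= 1.0):
            raise ValueError("collapse_threshold must be in [0,1]")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0,1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class Prediction:
    family_id: str
    id1: str
    id2: str
    pair: CandidatePair
    collapse: CollapseResult | None = None
    lrt: LrtResult | None = None
    combined_split: bool = False
    ambiguity: str = ""
    chain: str = ""


def _family_seed(base: int, index: int) -> int:
    return (base + 10007 * (index + 1)) % (2 ** 31)


def _combined(config: RunConfig, collapse: CollapseResult | None,
              lrt: LrtResult | None) -> bool:
    if config.mode == "collapse":
        return bool(collapse and collapse.is_split)
    if config.mode == "lrt":
        return bool(lrt and lrt.is_split)
    return bool(collapse and collapse.is_split and lrt and lrt.is_split)


def analyze_family(family: GeneFamily, config: RunConfig,
                   msa: Alignment | None = None,
                   tree=None, model: SubstModel | None = None,
                   seed: int | None = None) -> list[Prediction]:
    """Run the configured tests on every candidate pair of one family.

    Families with fewer than four members are skipped (no informative
    unrooted topology question below four taxa).  A precomputed ``msa`` and
    support-annotated ``tree`` are used when given; otherwise the built-in
    engine (or configured adapters) produces them.
    """
    if len(family) < 4:
        log.info("family %s skipped: %d members (< 4)", family.family_id,
                 len(family))
        return []
    if model is None:
        model = get_model(config.model)
    if seed is None:
        seed = config.seed
    if msa is None:
        seqs = list(family)
        if config.aligner_command:
            msa = ExternalTool("aligner", config.aligner_command).align(seqs)
        else:
            msa = progressive_align(seqs)
    msa = msa.subset([s.id for s in family]).without_allgap_columns()
    location_map = (read_location_map(config.location_map)
                    if config.location_map else None)
    pairs = enumerate_candidates(family, msa, min_len=config.min_len,
                                 max_frac=config.max_overlap_frac,
                                 location_map=location_map)
    if not pairs:
        return []
    need_collapse = config.mode in ("collapse", "intersection")
    if need_collapse and tree is None:
        if config.treebuilder_command:
            tree = ExternalTool(
                "treebuilder", config.treebuilder_command).build_tree(msa)
        else:
            fit = build_tree(msa, model, seed=seed)
            tree = bootstrap_supports(msa, model, fit.tree,
                                      n_reps=config.n_boot, seed=seed,
                                      rebuild=config.support_rebuild)
    predictions: list[Prediction] = []
    for k, pair in enumerate(pairs):
        collapse = (collapse_test(tree, pair, config.collapse_threshold)
                    if need_collapse else None)
        lrt = None
        if config.mode in ("lrt", "intersection"):
            lrt = lrt_test(msa, pair, model, alpha=config.alpha,
                           n=config.n_boot, seed=seed + 1000 * (k + 1),
                           mode=config.replicate_mode,
                           max_frac=config.max_overlap_frac)
        predictions.append(Prediction(
            family_id=family.family_id, id1=pair.id1, id2=pair.id2,
            pair=pair, collapse=collapse, lrt=lrt,
            combined_split=_combined(config, collapse, lrt)))
    classify_ambiguity(predictions, msa,
                       max_frac=config.max_overlap_frac)
    return predictions


def classify_ambiguity(predictions: list[Prediction], msa: Alignment,
                       max_frac: float = 0.1) -> list[Prediction]:
    """Label combined split predictions of one family.

    Predictions sharing a gene conflict when the two partner fragments
    overlap at >= ``max_frac`` of either (they claim the same stretch of the
    putative full-length gene); conflict components are labelled ambiguous,
    everything else unambiguous.  Compatible multi-piece splits are reported
    as an ordered chain of fragments.
    """
    split_preds = [p for p in predictions if p.combined_split]
    for p in split_preds:
        p.ambiguity = UNAMBIGUOUS
    # conflict edges between predictions sharing a gene with overlapping partners
    adj: dict[int, set[int]] = {i: set() for i in range(len(split_preds))}
    for i in range(len(split_preds)):
        for j in range(i + 1, len(split_preds)):
            a, b = split_preds[i], split_preds[j]
            shared = {a.id1, a.id2} & {b.id1, b.id2}
            if len(shared) != 1:
                continue
            g = shared.pop()
            pa = a.id2 if a.id1 == g else a.id1
            pb = b.id2 if b.id1 == g else b.id1
            if not passes_overlap_filter(aligned_overlap(msa, pa, pb),
                                         max_frac):
                adj[i].add(j)
                adj[j].add(i)
    # propagate through conflict components
    seen: set[int] = set()
    for i in range(len(split_preds)):
        if i in seen or not adj[i]:
            continue
        comp, stack = set(), [i]
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k])
        seen |= comp
        for k in comp:
            split_preds[k].ambiguity = AMBIGUOUS
    _annotate_chains(split_preds, msa)
    return predictions


def _annotate_chains(split_preds: list[Prediction], msa: Alignment) -> None:
    """Report compatible multi-piece splits as an ordered fragment chain."""
    unamb = [p for p in split_preds if p.ambiguity == UNAMBIGUOUS]
    genes: dict[str, set[str]] = {}
    for p in unamb:
        genes.setdefault(p.id1, set()).add(p.id2)
        genes.setdefault(p.id2, set()).add(p.id1)
    for p in unamb:
        members = {p.id1, p.id2}
        frontier = list(members)
        while frontier:
            g = frontier.pop()
            for other in genes.get(g, ()):
                if other not in members:
                    members.add(other)
                    frontier.append(other)
        if len(members) > 2:
            ordered = sorted(members,
                             key=lambda g: (int(msa.occupancy(g)[0]), g))
            p.chain = "->".join(ordered)


def _prediction_row(p: Prediction, config: RunConfig) -> dict:
    return {
        "family_id": p.family_id, "id1": p.id1, "id2": p.id2,
        "l1": p.pair.stats.l1, "l2": p.pair.stats.l2, "a12": p.pair.stats.a12,
        "collapse_support_threshold": (config.collapse_threshold
                                       if p.collapse else ""),
        "collapse_is_split": ("" if p.collapse is None
                              else str(p.collapse.is_split)),
        "T0": "" if p.lrt is None else format(p.lrt.T0, ".6g"),
        "n_boot": "" if p.lrt is None else p.lrt.n_boot,
        "p_B": "" if p.lrt is None else format(p.lrt.p_B, ".6g"),
        "alpha": "" if p.lrt is None else p.lrt.alpha,
        "lrt_is_split": "" if p.lrt is None else str(p.lrt.is_split),
        "combined_split": str(p.combined_split),
        "ambiguity": p.ambiguity,
        "chain": p.chain,
    }


def predictions_frame(predictions: Iterable[Prediction], config: RunConfig
                      ) -> pd.DataFrame:
    rows = [_prediction_row(p, config) for p in predictions]
    return pd.DataFrame(rows, columns=PREDICTIONS_COLUMNS)


def run(config: RunConfig, fasta_paths: list, family_map_path,
        out_dir, alignments_dir=None) -> pd.DataFrame:
    """Full pipeline over a dataset; writes the report files.

    Outputs in ``out_dir``: ``predictions.tsv`` (one row per candidate
    pair), ``summary.tsv`` (per-family and per-ambiguity-class counts) and
    ``failures.log``.  Per-family failures are logged and surfaced there;
    they never abort the run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs = []
    for path in fasta_paths:
        seqs.extend(read_fasta(path))
    family_map = read_family_map(family_map_path)
    families = assemble_families(seqs, family_map, config.target_genome)
    model = get_model(config.model)
    all_preds: list[Prediction] = []
    failures: list[str] = []
    for idx, family in enumerate(sorted(families, key=lambda f: f.family_id)):
        msa = None
        if alignments_dir is not None:
            cand = Path(alignments_dir) / f"{family.family_id}.fa"
            if cand.exists():
                msa = read_alignment(cand)
        t0 = time.monotonic()
        fam_seed = _family_seed(config.seed, idx)
        try:
            preds = analyze_family(family, config, msa=msa, model=model,
                                   seed=fam_seed)
        except Exception as exc:
            log.exception("family %s failed", family.family_id)
            failures.append(f"{family.family_id}\t{exc}")
            continue
        log.info("family %s: %d candidate pairs, %.1fs, seed %d",
                 family.family_id, len(preds), time.monotonic() - t0, fam_seed)
        all_preds.extend(preds)
    frame = predictions_frame(all_preds, config)
    frame.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)
    summary = summarize(all_preds)
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    with open(out_dir / "failures.log", "w") as fh:
        fh.write("\n".join(failures) + ("\n" if failures else ""))
    config.to_yaml(out_dir / "config.yaml")
    return frame


def union_call_sets(*frames: pd.DataFrame) -> pd.DataFrame:
    """Post-hoc union of split-gene call sets (e.g. with an external
    pairwise method's predictions): deduplicated on (family_id, id1, id2),
    keeping the first frame's row for pairs called by several methods.
    Frames only need the id columns plus ``combined_split``."""
    calls = []
    for frame in frames:
        f = frame[frame["combined_split"].astype(str) == "True"]
        calls.append(f)
    merged = pd.concat(calls, ignore_index=True) if calls else pd.DataFrame(
        columns=PREDICTIONS_COLUMNS)
    merged = merged.drop_duplicates(subset=["family_id", "id1", "id2"],
                                    keep="first")
    return merged.sort_values(["family_id", "id1", "id2"]).reset_index(
        drop=True)


def summarize(predictions: list[Prediction]) -> pd.DataFrame:
    rows = []
    by_family: dict[str, list[Prediction]] = {}
    for p in predictions:
        by_family.setdefault(p.family_id, []).append(p)
    for fam in sorted(by_family):
        preds = by_family[fam]
        rows.append({
            "family_id": fam,
            "n_candidate_pairs": len(preds),
            "n_split": sum(p.combined_split for p in preds),
            "n_unambiguous": sum(p.ambiguity == UNAMBIGUOUS for p in preds),
            "n_ambiguous": sum(p.ambiguity == AMBIGUOUS for p in preds),
        })
    rows.append({
        "family_id": "TOTAL",
        "n_candidate_pairs": len(predictions),
        "n_split": sum(p.combined_split for p in predictions),
        "n_unambiguous": sum(p.ambiguity == UNAMBIGUOUS for p in predictions),
        "n_ambiguous": sum(p.ambiguity == AMBIGUOUS for p in predictions),
    })
    return pd.DataFrame(rows, columns=["family_id", "n_candidate_pairs",
                                       "n_split", "n_unambiguous",
                                       "n_ambiguous"])
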