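"""Synthetic gene families with planted split genes and paralog negatives.

Families of protein sequences are evolved site-independently along a species
tree under the engine's substitution model (no indels, so the true alignment
is the trivial columnwise one).  Positive cases split the target genome's
gene at a random position into two fragments of at least ``min_frag``
residues.  Negative cases emulate the classic confounder - complementary
fragments of two paralogous genes: a duplication is placed on the target's
ancestral lineage ``dup_depth`` substitutions/site above the present, the
second copy re-evolves independently from the ancestral sequence at that
point, and the pair keeps the N-terminal piece of the original gene and the
C-terminal piece of the duplicate.  A deep duplication (above the nearest
reference divergences) makes the copies attach at genuinely different tree
positions and therefore detectable; as ``dup_depth`` approaches zero the
copies become species-specific and finally identical - indistinguishable
from a true split by any homology-based method.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqdata import AA_ORDER, GAP, Alignment, GeneFamily, ProteinSequence
from .substmodels import SubstModel, get_model
from .trees import PhyloTree, TreeNode

TRUE_SPLIT = "true_split"
PARALOG_NEGATIVE = "paralog_negative"


@dataclass
class SimScenario:
    """Study conditions for one simulated dataset."""

    n_refs: int = 8
    seq_length: int = 400
    model: str = "LG"
    n_positive: int = 30
    n_negative: int = 30
    dup_depth: float = 0.4
    branch_length_range: tuple[float, float] = (0.05, 0.3)
    min_frag: int = 50
    min_parent_length: int = 100
    target_genome: str = "T"
    seed: int = 0

    def __post_init__(self):
        if self.seq_length < self.min_parent_length:
            raise ValueError("genes shorter than the minimum parent length")
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class TruthSet:
    """Ground-truth labels for planted pairs."""

    labels: dict[tuple[str, str], str] = field(default_factory=dict)
    split_positions: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, id_a: str, id_b: str, label: str, position: int) -> None:
        key = tuple(sorted((id_a, id_b)))
        if key in self.labels:
            raise ValueError(f"pair {key} planted twice")
        self.labels[key] = label
        self.split_positions[key] = position

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id1\tid2\tlabel\tsplit_position\n")
            for key in sorted(self.labels):
                fh.write(f"{key[0]}\t{key[1]}\t{self.labels[key]}"
                         f"\t{self.split_positions[key]}\n")

    @classmethod
    def from_tsv(cls, path) -> "TruthSet":
        out = cls()
        with open(path) as fh:
            fh.readline()
            for line in fh:
                a, b, label, pos = line.rstrip("\n").split("\t")
                out.add(a, b, label, int(pos))
        return out


# ---- species tree and sequence evolution --------------------------------

def _balanced(names: list[str]) -> TreeNode:
    if len(names) == 1:
        return TreeNode(names[0])
    mid = (len(names) + 1) // 2
    node = TreeNode()
    node.add_child(_balanced(names[:mid]))
    node.add_child(_balanced(names[mid:]))
    return node


def species_tree(n_refs: int = 8, seed: int = 0,
                 branch_length_range: tuple[float, float] = (0.05, 0.3),
                 target_genome: str = "T") -> PhyloTree:
    """Balanced reference topology with the target attached to the first
    reference; branch lengths uniform on the configured range."""
    rng = np.random.default_rng(seed)
    refs = [f"R{i + 1}" for i in range(n_refs)]
    root = _balanced(refs)
    tree = PhyloTree(root)
    first = tree.find_leaf(refs[0])
    first.name = None
    first.add_child(TreeNode(refs[0]))
    first.add_child(TreeNode(target_genome))
    for node in tree.postorder():
        if node.parent is not None:
            node.length = float(rng.uniform(*branch_length_range))
    return tree


def _sample_states(parent: np.ndarray, P: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    probs = P[parent]                     # (L, 20)
    cum = np.cumsum(probs, axis=1)
    cum /= cum[:, -1:]
    u = rng.random(len(parent))
    return (cum < u[:, None]).sum(axis=1).astype(np.int8)


def _decode(states: np.ndarray) -> str:
    return "".join(AA_ORDER[s] for s in states)


def evolve_sequence(parent: np.ndarray, t: float, model: SubstModel,
                    rng: np.random.Generator) -> np.ndarray:
    if t == 0:
        return parent.copy()
    return _sample_states(parent, model.transition_matrix(t), rng)


def evolve_family(tree: PhyloTree, length: int, model: SubstModel, seed: int,
                  family_id: str = "fam", target_genome: str = "T"
                  ) -> tuple[GeneFamily, Alignment, dict[int, np.ndarray]]:
    """Evolve one gene per leaf; returns the family, the (trivial) true
    alignment, and the ancestral sequences keyed by node identity."""
    rng = np.random.default_rng(seed)
    node_seqs: dict[int, np.ndarray] = {}
    root_states = rng.choice(20, size=length, p=model.pi).astype(np.int8)
    members: "OrderedDict[str, ProteinSequence]" = OrderedDict()
    rows: "OrderedDict[str, str]" = OrderedDict()
    for node in tree.preorder():
        if node.parent is None:
            node_seqs[id(node)] = root_states
        else:
            node_seqs[id(node)] = evolve_sequence(
                node_seqs[id(node.parent)], node.length, model, rng)
        if node.is_leaf:
            gene_id = f"{node.name}_{family_id}"
            residues = _decode(node_seqs[id(node)])
            members[gene_id] = ProteinSequence(id=gene_id, residues=residues,
                                               genome=node.name)
            rows[gene_id] = residues
    family = GeneFamily(family_id=family_id, members=members,
                        target_genome=target_genome)
    return family, Alignment(rows), node_seqs


# ---- planting ------------------------------------------------------------

def _fragment_rows(residues: str, other: str, s: int) -> tuple[str, str]:
    L = len(residues)
    row1 = residues[:s] + GAP * (L - s)
    row2 = GAP * s + other[s:]
    return row1, row2


def plant_split(family: GeneFamily, alignment: Alignment, target_id: str,
                seed: int, min_frag: int = 50,
                truth: TruthSet | None = None
                ) -> tuple[GeneFamily, Alignment, TruthSet]:
    """Replace the target gene by two fragments cut at a uniform position.

    The cut s is uniform on [min_frag, L - min_frag] so both pieces keep at
    least ``min_frag`` residues; genes shorter than 2*min_frag are refused.
    """
    gene = family.members[target_id]
    L = gene.length
    if L < 2 * min_frag:
        raise ValueError(f"gene {target_id} too short to split ({L} aa)")
    rng = np.random.default_rng(seed)
    s = int(rng.integers(min_frag, L - min_frag + 1))
    id1, id2 = f"{target_id}_f1", f"{target_id}_f2"
    row = alignment.rows[target_id]
    row1, row2 = _fragment_rows(row, row, s)
    members = OrderedDict()
    rows = OrderedDict()
    for gid, seq in family.members.items():
        if gid == target_id:
            members[id1] = ProteinSequence(id1, gene.residues[:s], gene.genome)
            members[id2] = ProteinSequence(id2, gene.residues[s:], gene.genome)
            rows[id1], rows[id2] = row1, row2
        else:
            members[gid] = seq
            rows[gid] = alignment.rows[gid]
    truth = truth if truth is not None else TruthSet()
    truth.add(id1, id2, TRUE_SPLIT, s)
    return (GeneFamily(family.family_id, members, family.target_genome),
            Alignment(rows), truth)


def _bridge_sample(top: np.ndarray, bottom: np.ndarray, t1: float, t2: float,
                   model: SubstModel, rng: np.random.Generator) -> np.ndarray:
    """Sample the state at an interior point of a branch, conditioned on the
    realized states at both ends (t1 above the point, t2 below)."""
    P1 = model.transition_matrix(max(t1, 0.0))
    P2 = model.transition_matrix(max(t2, 0.0))
    probs = P1[top] * P2[:, bottom].T     # (L, 20)
    cum = np.cumsum(probs, axis=1)
    cum /= cum[:, -1:]
    u = rng.random(len(top))
    return (cum < u[:, None]).sum(axis=1).astype(np.int8)


def _duplication_point(tree: PhyloTree, node_seqs: dict[int, np.ndarray],
                       target_genome: str, depth: float,
                       model: SubstModel, rng: np.random.Generator
                       ) -> np.ndarray:
    """Ancestral sequence on the target lineage ``depth`` subs/site above the
    tip (clamped at the root)."""
    node = tree.find_leaf(target_genome)
    remaining = depth
    while node.parent is not None and remaining > 0:
        if node.length >= remaining:
            return _bridge_sample(node_seqs[id(node.parent)],
                                  node_seqs[id(node)],
                                  node.length - remaining, remaining,
                                  model, rng)
        remaining -= node.length
        node = node.parent
    return node_seqs[id(node)].copy()


def plant_paralog_pair(family: GeneFamily, alignment: Alignment,
                       tree: PhyloTree, node_seqs: dict[int, np.ndarray],
                       target_id: str, dup_depth: float, seed: int,
                       model: SubstModel, min_frag: int = 50,
                       truth: TruthSet | None = None
                       ) -> tuple[GeneFamily, Alignment, TruthSet]:
    """Replace the target gene by complementary fragments of two paralogs.

    A duplicate lineage branches off the target's ancestry ``dup_depth``
    subs/site above the present and evolves back to the present; the planted
    pair is the N-terminal piece of the original gene plus the C-terminal
    piece of the duplicate, cut at the same uniform position (so the
    fragments are non-overlapping by construction).  ``dup_depth = 0`` gives
    fragments of identical copies - the hardest negative.
    """
    gene = family.members[target_id]
    L = gene.length
    if L < 2 * min_frag:
        raise ValueError(f"gene {target_id} too short to cut ({L} aa)")
    rng = np.random.default_rng(seed)
    ancestor = _duplication_point(tree, node_seqs, gene.genome, dup_depth,
                                  model, rng)
    copy2 = evolve_sequence(ancestor, dup_depth, model, rng)
    s = int(rng.integers(min_frag, L - min_frag + 1))
    id1, id2 = f"{target_id}_f1", f"{target_id}_f2"
    copy2_res = _decode(copy2)
    row1, row2 = _fragment_rows(alignment.rows[target_id], copy2_res, s)
    members = OrderedDict()
    rows = OrderedDict()
    for gid, seq in family.members.items():
        if gid == target_id:
            members[id1] = ProteinSequence(id1, gene.residues[:s], gene.genome)
            members[id2] = ProteinSequence(id2, copy2_res[s:], gene.genome)
            rows[id1], rows[id2] = row1, row2
        else:
            members[gid] = seq
            rows[gid] = alignment.rows[gid]
    truth = truth if truth is not None else TruthSet()
    truth.add(id1, id2, PARALOG_NEGATIVE, s)
    return (GeneFamily(family.family_id, members, family.target_genome),
            Alignment(rows), truth)


# ---- dataset assembly and scoring ---------------------------------------

@dataclass
class SimDataset:
    families: list[GeneFamily]
    alignments: dict[str, Alignment]
    truth: TruthSet
    scenario: SimScenario


def build_dataset(scenario: SimScenario) -> SimDataset:
    """Simulate ``n_positive`` split families and ``n_negative`` paralog
    families; per-family branch lengths are redrawn from the configured
    range, emulating among-family rate variation."""
    model = get_model(scenario.model)
    families: list[GeneFamily] = []
    alignments: dict[str, Alignment] = {}
    truth = TruthSet()
    total = scenario.n_positive + scenario.n_negative
    for k in range(total):
        fam_id = f"fam{k:03d}"
        fam_seed = (scenario.seed + 97 * (k + 1)) % (2 ** 31)
        tree = species_tree(scenario.n_refs, seed=fam_seed,
                            branch_length_range=scenario.branch_length_range,
                            target_genome=scenario.target_genome)
        family, aln, node_seqs = evolve_family(
            tree, scenario.seq_length, model, seed=fam_seed + 1,
            family_id=fam_id, target_genome=scenario.target_genome)
        target_id = f"{scenario.target_genome}_{fam_id}"
        if k < scenario.n_positive:
            family, aln, truth = plant_split(
                family, aln, target_id, seed=fam_seed + 2,
                min_frag=scenario.min_frag, truth=truth)
        else:
            family, aln, truth = plant_paralog_pair(
                family, aln, tree, node_seqs, target_id,
                dup_depth=scenario.dup_depth, seed=fam_seed + 2,
                model=model, min_frag=scenario.min_frag, truth=truth)
        families.append(family)
        alignments[fam_id] = aln
    return SimDataset(families=families, alignments=alignments, truth=truth,
                      scenario=scenario)


def write_dataset(ds: SimDataset, out_dir) -> None:
    """Emit FASTA per genome, family map TSV, true alignments, truth TSV
    and a scenario snapshot."""
    from .seqdata import write_alignment, write_fasta
    import yaml
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    by_genome: dict[str, list[ProteinSequence]] = {}
    with open(out / "families.tsv", "w") as fh:
        fh.write("gene_id\tgenome_id\tfamily_id\n")
        for fam in ds.families:
            for seq in fam:
                fh.write(f"{seq.id}\t{seq.genome}\t{fam.family_id}\n")
                by_genome.setdefault(seq.genome, []).append(seq)
    for genome in sorted(by_genome):
        write_fasta(by_genome[genome], out / f"{genome}.fa")
    for fam_id, aln in ds.alignments.items():
        write_alignment(aln, out / "alignments" / f"{fam_id}.fa")
    ds.truth.to_tsv(out / "truth.tsv")
    payload = {**ds.scenario.__dict__}
    payload["branch_length_range"] = list(payload["branch_length_range"])
    with open(out / "scenario.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def run_scenario(scenario: SimScenario, config=None) -> dict:
    """Simulate a dataset, run the pipeline on the true alignments, score it.

    Returns the evaluation dict plus the predictions and truth for audit.
    """
    from .pipeline import RunConfig, analyze_family, predictions_frame
    from .pipeline import _family_seed
    if config is None:
        config = RunConfig()
    config.target_genome = scenario.target_genome
    ds = build_dataset(scenario)
    model = get_model(config.model)
    predictions = []
    for idx, family in enumerate(sorted(ds.families,
                                        key=lambda f: f.family_id)):
        preds = analyze_family(family, config,
                               msa=ds.alignments[family.family_id],
                               model=model,
                               seed=_family_seed(config.seed, idx))
        predictions.extend(preds)
    called = [(p.id1, p.id2) for p in predictions if p.combined_split]
    metrics = evaluate(called, ds.truth)
    return {"metrics": metrics, "predictions": predictions,
            "dataset": ds, "frame": predictions_frame(predictions, config)}


def evaluate(predicted_pairs, truth: TruthSet) -> dict:
    """Precision/recall of predicted pairs against the planted truth.

    TP: predicted pairs planted as true splits; FP: predicted pairs planted
    as paralog negatives or never planted; FN: true splits not predicted.
    With no predictions, precision is undefined and reported as None.
    """
    if not truth.labels:
        raise ValueError("empty truth set")
    predicted = {tuple(sorted(p)) for p in predicted_pairs}
    positives = {k for k, v in truth.labels.items() if v == TRUE_SPLIT}
    negatives = {k for k, v in truth.labels.items() if v == PARALOG_NEGATIVE}
    tp = len(predicted & positives)
    fp = len(predicted - positives)
    fn = len(positives - predicted)
    out = {
        "tp": tp, "fp": fp, "fn": fn,
        "n_positive": len(positives), "n_negative": len(negatives),
        "fp_on_negatives": len(predicted & negatives),
        "recall": tp / len(positives) if positives else None,
        "precision": tp / (tp + fp) if predicted else None,
        "fp_rate_negatives": (len(predicted & negatives) / len(negatives)
                              if negatives else None),
    }
    return out
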