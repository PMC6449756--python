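import numpy as np
import pytest
from scipy.stats import chisquare

from splitgene.candidates import aligned_overlap, enumerate_candidates
from splitgene.seqdata import AA_ORDER
from splitgene.synthetic import (PARALOG_NEGATIVE, TRUE_SPLIT, SimScenario,
                                 TruthSet, build_dataset, evaluate,
                                 evolve_family, plant_paralog_pair,
                                 plant_split, species_tree)
from splitgene.trees import PhyloTree, TreeNode


class TestEvolveFamily:
    def test_zero_branch_lengths_copy_the_root(self, lg):
        tree = species_tree(4, seed=0)
        for n in tree.postorder():
            if n.parent is not None:
                n.length = 0.0
        fam, aln, node_seqs = evolve_family(tree, 100, lg, seed=1)
        rows = set(aln.rows.values())
        assert len(rows) == 1

    def test_deterministic_under_seed(self, lg):
        tree = species_tree(4, seed=0)
        a = evolve_family(tree, 80, lg, seed=7)[1]
        b = evolve_family(tree, 80, lg, seed=7)[1]
        assert a.rows == b.rows

    def test_long_branches_reach_stationary_identity(self, lg):
        root = TreeNode()
        root.add_child(TreeNode("A", 5.0))
        root.add_child(TreeNode("B", 5.0))
        tree = PhyloTree(root)
        fam, aln, _ = evolve_family(tree, 10000, lg, seed=3,
                                    target_genome="A")
        ra, rb = aln.rows["A_fam"], aln.rows["B_fam"]
        identity = np.mean([a == b for a, b in zip(ra, rb)])
        expected = float((lg.pi ** 2).sum())
        assert abs(identity - expected) < 3 * np.sqrt(expected / 10000)

    def test_leaves_carry_genome_labels(self, lg):
        tree = species_tree(3, seed=2)
        fam, _, _ = evolve_family(tree, 60, lg, seed=2, family_id="x")
        assert {s.genome for s in fam} == {"R1", "R2", "R3", "T"}
        assert len(fam.target_members) == 1


class TestPlantSplit:
    def _family(self, lg, length=300, seed=11):
        tree = species_tree(4, seed=seed)
        return evolve_family(tree, length, lg, seed=seed + 1,
                             family_id="fam")

    def test_boundary_length_forces_midpoint(self, lg):
        fam, aln, _ = self._family(lg, length=100)
        fam2, aln2, truth = plant_split(fam, aln, "T_fam", seed=1)
        f1 = fam2.members["T_fam_f1"]
        f2 = fam2.members["T_fam_f2"]
        assert f1.length == 50 and f2.length == 50

    def test_fragments_partition_the_parent(self, lg):
        fam, aln, _ = self._family(lg)
        parent = fam.members["T_fam"].residues
        fam2, aln2, truth = plant_split(fam, aln, "T_fam", seed=2)
        f1 = fam2.members["T_fam_f1"].residues
        f2 = fam2.members["T_fam_f2"].residues
        assert f1 + f2 == parent
        assert min(len(f1), len(f2)) >= 50

    def test_too_short_gene_rejected(self, lg):
        fam, aln, _ = self._family(lg, length=100)
        with pytest.raises(ValueError, match="too short"):
            plant_split(fam, aln, "T_fam", seed=3, min_frag=51)

    def test_cut_position_uniform(self, lg):
        # statistical oracle: chi-square over 20 bins of s ~ U[50, 250]
        fam, aln, _ = self._family(lg, length=300)
        draws = np.empty(10000, dtype=int)
        for i in range(10000):
            truth = plant_split(fam, aln, "T_fam", seed=i)[2]
            draws[i] = next(iter(truth.split_positions.values()))
        assert draws.min() >= 50 and draws.max() <= 250
        hist, _ = np.histogram(draws, bins=20, range=(50, 251))
        _, p = chisquare(hist)
        assert p > 1e-4

    def test_planted_fragments_pass_candidate_filters(self, lg):
        fam, aln, _ = self._family(lg)
        fam2, aln2, _ = plant_split(fam, aln, "T_fam", seed=5)
        pairs = enumerate_candidates(fam2, aln2)
        assert [(p.id1, p.id2) for p in pairs] == [("T_fam_f1", "T_fam_f2")]
        assert pairs[0].stats.a12 == 0


class TestPlantParalogPair:
    def _family(self, lg, seed=31):
        tree = species_tree(6, seed=seed)
        fam, aln, node_seqs = evolve_family(tree, 300, lg, seed=seed + 1,
                                            family_id="fam")
        return tree, fam, aln, node_seqs

    def test_zero_depth_copies_equal_parent(self, lg):
        tree, fam, aln, node_seqs = self._family(lg)
        parent = fam.members["T_fam"].residues
        fam2, aln2, truth = plant_paralog_pair(
            fam, aln, tree, node_seqs, "T_fam", dup_depth=0.0, seed=1,
            model=lg)
        f1 = fam2.members["T_fam_f1"].residues
        f2 = fam2.members["T_fam_f2"].residues
        assert f1 + f2 == parent  # indistinguishable from a true split
        key = tuple(sorted(("T_fam_f1", "T_fam_f2")))
        assert truth.labels[key] == PARALOG_NEGATIVE

    def test_fragments_never_overlap_in_alignment(self, lg):
        tree, fam, aln, node_seqs = self._family(lg)
        fam2, aln2, _ = plant_paralog_pair(
            fam, aln, tree, node_seqs, "T_fam", dup_depth=0.4, seed=2,
            model=lg)
        stats = aligned_overlap(aln2, "T_fam_f1", "T_fam_f2")
        assert stats.a12 == 0

    def test_deep_duplication_matches_expected_identity(self, lg):
        tree, fam, aln, node_seqs = self._family(lg)
        depth = 3.0
        # the duplication clamps at the root, so parent and duplicate are
        # separated by (root-to-tip distance) + depth substitutions/site
        node = tree.find_leaf("T")
        to_root = 0.0
        while node.parent is not None:
            to_root += node.length
            node = node.parent
        P = lg.transition_matrix(to_root + depth)
        expected = float((lg.pi * np.diag(P)).sum())
        draws = []
        for seed in range(30):
            fam2, _, truth = plant_paralog_pair(
                fam, aln, tree, node_seqs, "T_fam", dup_depth=depth,
                seed=seed, model=lg)
            s = next(iter(truth.split_positions.values()))
            parent_tail = fam.members["T_fam"].residues[s:]
            dup_tail = fam2.members["T_fam_f2"].residues
            draws.append(np.mean([a == b for a, b in
                                  zip(parent_tail, dup_tail)]))
        assert abs(np.mean(draws) - expected) < 0.02
        assert expected < 2 * float((lg.pi ** 2).sum())  # near saturation


class TestTruthAndEvaluate:
    def test_pair_planted_twice_rejected(self):
        t = TruthSet()
        t.add("a", "b", TRUE_SPLIT, 50)
        with pytest.raises(ValueError, match="twice"):
            t.add("b", "a", PARALOG_NEGATIVE, 60)

    def test_tsv_roundtrip(self, tmp_path):
        t = TruthSet()
        t.add("a", "b", TRUE_SPLIT, 50)
        t.add("c", "d", PARALOG_NEGATIVE, 70)
        p = tmp_path / "truth.tsv"
        t.to_tsv(p)
        back = TruthSet.from_tsv(p)
        assert back.labels == t.labels
        assert back.split_positions == t.split_positions

    def test_perfect_calls(self):
        t = TruthSet()
        for i in range(10):
            t.add(f"g{i}_f1", f"g{i}_f2", TRUE_SPLIT, 60)
        predicted = list(t.labels)
        m = evaluate(predicted, t)
        assert m["precision"] == 1.0 and m["recall"] == 1.0

    def test_no_predictions_convention(self):
        t = TruthSet()
        t.add("a", "b", TRUE_SPLIT, 60)
        m = evaluate([], t)
        assert m["recall"] == 0.0 and m["precision"] is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_confusion_matrix_count(self, seed):
        rng = np.random.default_rng(seed)
        t = TruthSet()
        pos, neg = [], []
        for i in range(20):
            key = (f"g{i}_f1", f"g{i}_f2")
            if rng.random() < 0.5:
                t.add(*key, TRUE_SPLIT, 60)
                pos.append(key)
            else:
                t.add(*key, PARALOG_NEGATIVE, 60)
                neg.append(key)
        predicted = [k for k in t.labels if rng.random() < 0.6]
        predicted.append(("x_f1", "x_f2"))  # unplanted prediction counts FP
        m = evaluate(predicted, t)
        tp = sum(1 for k in predicted if k in pos)
        assert m["tp"] == tp
        assert m["fp"] == len(predicted) - tp
        assert m["fn"] == len(pos) - tp
        if pos:
            assert m["recall"] == tp / len(pos)


class TestBuildDataset:
    def test_counts_and_determinism(self, lg):
        sc = SimScenario(n_refs=4, seq_length=150, n_positive=2, n_negative=2,
                         dup_depth=0.3, seed=5)
        ds1 = build_dataset(sc)
        ds2 = build_dataset(sc)
        assert len(ds1.families) == 4
        labels = list(ds1.truth.labels.values())
        assert labels.count(TRUE_SPLIT) == 2
        assert labels.count(PARALOG_NEGATIVE) == 2
        assert {f.family_id: f.members.keys() for f in ds1.families} == \
               {f.family_id: f.members.keys() for f in ds2.families}
        a1 = {k: v.rows for k, v in ds1.alignments.items()}
        a2 = {k: v.rows for k, v in ds2.alignments.items()}
        assert a1 == a2

    def test_every_family_has_planted_pair_passing_filters(self, lg):
        sc = SimScenario(n_refs=4, seq_length=150, n_positive=3, n_negative=3,
                         dup_depth=0.4, seed=8)
        ds = build_dataset(sc)
        for fam in ds.families:
            pairs = enumerate_candidates(fam, ds.alignments[fam.family_id])
            assert len(pairs) == 1
            key = (pairs[0].id1, pairs[0].id2)
            assert key in ds.truth.labels
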