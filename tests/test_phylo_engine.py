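import subprocess

import numpy as np
import pytest

from splitgene.adapters import AdapterError, ExternalTool, fasttree_adapter, \
    mafft_adapter
from splitgene.aligner import progressive_align
from splitgene.likelihood import (MIN_BL, TreeLikelihood, compress_alignment,
                                  log_likelihood, optimize_branch_lengths)
from splitgene.seqdata import AA_INDEX, AA_ORDER, Alignment, ProteinSequence
from splitgene.substmodels import get_model, load_lg, poisson_model
from splitgene.synthetic import evolve_sequence, species_tree, _decode
from splitgene.trees import PhyloTree, TreeNode, parse_newick
from splitgene.treesearch import build_tree, bootstrap_supports

from conftest import random_alignment
from oracles import exhaustive_log_likelihood


class TestSubstModel:
    def test_lg_is_a_valid_reversible_model(self, lg):
        assert np.abs(lg.Q.sum(axis=1)).max() < 1e-10
        assert abs(-(lg.pi * np.diag(lg.Q)).sum() - 1.0) < 1e-10
        flux = lg.pi[:, None] * lg.Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_transition_matrix_rows_sum_to_one(self, lg):
        for t in (0.0, 0.01, 0.5, 5.0):
            P = lg.transition_matrix(t)
            assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
            assert (P >= 0).all()

    def test_long_time_approaches_stationarity(self, lg):
        P = lg.transition_matrix(50.0)
        assert np.abs(P - lg.pi[None, :]).max() < 1e-6

    def test_gamma_categories_mean_one(self, lg):
        g = lg.with_gamma(4, alpha=0.7)
        assert g.n_rates == 4
        assert abs(g.rates.mean() - 1.0) < 1e-12


class TestPruningLikelihood:
    def test_matches_exhaustive_oracle_with_gaps(self, lg):
        rng = np.random.default_rng(1)
        aln = random_alignment(rng, list("ABCD"), 8, gap_frac=0.25)
        tree = parse_newick("((A:0.1,B:0.2):0.15,C:0.3,D:0.05);")
        assert abs(log_likelihood(tree, aln, lg)
                   - exhaustive_log_likelihood(tree, aln, lg)) < 1e-8

    def test_single_leaf_closed_form(self, lg):
        aln = Alignment({"A": "MKV"})
        tree = parse_newick("A;")
        expected = sum(np.log(lg.pi[AA_INDEX[c]]) for c in "MKV")
        assert abs(log_likelihood(tree, aln, lg) - expected) < 1e-12

    def test_zero_distance_identical_pair_equals_single_sequence(self, lg):
        aln2 = Alignment({"A": "MKVW", "B": "MKVW"})
        tree2 = parse_newick("(A:0.0,B:0.0);")
        aln1 = Alignment({"A": "MKVW"})
        tree1 = parse_newick("A;")
        assert abs(log_likelihood(tree2, aln2, lg)
                   - log_likelihood(tree1, aln1, lg)) < 1e-10

    def test_allgap_column_contributes_zero(self, lg):
        base = Alignment({"A": "MK", "B": "ML", "C": "RK"})
        padded = Alignment({"A": "MK-", "B": "ML-", "C": "RK-"})
        tree = parse_newick("(A:0.1,B:0.2,C:0.3);")
        assert abs(log_likelihood(tree, base, lg)
                   - log_likelihood(tree, padded, lg)) < 1e-12

    def test_rerooting_invariance(self, lg):
        rng = np.random.default_rng(2)
        aln = random_alignment(rng, list("ABCDE"), 30, gap_frac=0.2)
        t1 = parse_newick(
            "((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.2,E:0.4);")
        # same unrooted tree rooted inside the A,B stem edge
        t2 = parse_newick(
            "(((C:0.3,D:0.05):0.2,E:0.4):0.075,(A:0.1,B:0.2):0.075);")
        assert abs(log_likelihood(t1, aln, lg)
                   - log_likelihood(t2, aln, lg)) < 1e-8

    def test_unset_branch_length_is_error(self, lg):
        aln = Alignment({"A": "M", "B": "K"})
        tree = parse_newick("(A,B);")
        with pytest.raises(ValueError, match="branch length"):
            log_likelihood(tree, aln, lg)

    def test_leaf_alignment_mismatch_is_error(self, lg):
        aln = Alignment({"A": "M", "B": "K"})
        tree = parse_newick("(A:0.1,Z:0.1);")
        with pytest.raises(ValueError, match="differ"):
            log_likelihood(tree, aln, lg)


class TestBranchOptimization:
    def test_identical_sequences_shrink_to_zero(self, lg):
        aln = Alignment({"A": "MKVW" * 25, "B": "MKVW" * 25})
        tree = parse_newick("(A:0.3,B:0.3);")
        fit = optimize_branch_lengths(tree, aln, lg)
        total = sum(n.length for n in fit.tree.postorder()
                    if n.parent is not None)
        assert total <= 1e-5

    def test_two_leaf_optimum_matches_grid_search(self, lg):
        rng = np.random.default_rng(3)
        a = rng.choice(list(AA_ORDER), 200)
        b = a.copy()
        flip = rng.random(200) < 0.3
        b[flip] = rng.choice(list(AA_ORDER), flip.sum())
        aln = Alignment({"A": "".join(a), "B": "".join(b)})
        tree = parse_newick("(A:0.1,B:0.1);")
        fit = optimize_branch_lengths(tree, aln, lg)
        # independent oracle: direct two-sequence likelihood on a fine grid
        ai = np.array([AA_INDEX[c] for c in aln.rows["A"]])
        bi = np.array([AA_INDEX[c] for c in aln.rows["B"]])
        grid = np.arange(1e-4, 2.0, 1e-4)
        best = max(
            float(np.log(lg.pi[ai] * lg.transition_matrix(t)[ai, bi]).sum())
            for t in grid)
        assert fit.log_likelihood >= best - 1e-6
        assert abs(fit.log_likelihood - best) < 1e-3

    def test_ascent_from_arbitrary_lengths(self, lg):
        rng = np.random.default_rng(4)
        aln = random_alignment(rng, list("ABCDEF"), 60, gap_frac=0.1)
        tree = parse_newick(
            "((A:1.5,B:0.01):0.9,(C:2.0,D:0.001):1.2,(E:0.5,F:0.5):0.3);")
        before = log_likelihood(tree, aln, lg)
        fit = optimize_branch_lengths(tree, aln, lg)
        assert fit.log_likelihood >= before
        # re-evaluating the returned tree reproduces the reported value
        assert abs(log_likelihood(fit.tree, aln, lg)
                   - fit.log_likelihood) < 1e-6


def _simulate_on_tree(tree, length, model, seed):
    rng = np.random.default_rng(seed)
    seqs = {}

    def walk(node, states):
        if node.parent is not None:
            states = evolve_sequence(states, node.length, model, rng)
        if node.is_leaf:
            seqs[node.name] = _decode(states)
        for c in node.children:
            walk(c, states)

    root_states = rng.choice(20, size=length, p=model.pi).astype(np.int8)
    walk(tree.root, root_states)
    return Alignment(seqs)


class TestBuildTree:
    def test_three_rows_single_topology(self, lg):
        aln = Alignment({"A": "MKVWMKVW" * 10, "B": "MKVWMKLW" * 10,
                         "C": "MRVWMKVW" * 10})
        fit = build_tree(aln, lg)
        assert set(fit.tree.leaf_names()) == {"A", "B", "C"}
        assert np.isfinite(fit.log_likelihood)

    def test_recovers_known_topology(self, lg):
        true = parse_newick(
            "((A:0.15,B:0.2):0.25,(C:0.1,D:0.3):0.2,E:0.4);")
        aln = _simulate_on_tree(true, 500, lg, seed=5)
        fit = build_tree(aln, lg, seed=0)
        assert fit.tree.bipartitions() == true.bipartitions()

    def test_start_topology_only_improves(self, lg):
        true = parse_newick(
            "((A:0.15,B:0.2):0.25,(C:0.1,D:0.3):0.2,E:0.4);")
        aln = _simulate_on_tree(true, 300, lg, seed=6)
        start_fit = optimize_branch_lengths(true, aln, lg)
        fit = build_tree(aln, lg, start=true, seed=0)
        assert fit.log_likelihood >= start_fit.log_likelihood - 1e-6

    def test_fewer_than_two_rows_is_error(self, lg):
        with pytest.raises(ValueError):
            build_tree(Alignment({"A": "MK"}), lg)


class TestBootstrapSupports:
    def test_supports_are_counts_over_n(self, lg):
        aln = Alignment({"A": "M" * 30, "B": "M" * 30,
                         "C": "K" * 30, "D": "K" * 30})
        fit = build_tree(aln, lg, seed=0)
        sup = bootstrap_supports(aln, lg, fit.tree, n_reps=10, seed=1)
        for n in sup.postorder():
            if n.support is not None:
                assert round(n.support * 10) == pytest.approx(n.support * 10)
                assert 0.0 <= n.support <= 1.0

    def test_strong_internal_branch_gets_high_support(self, lg):
        true = parse_newick("((A:0.1,B:0.1):0.5,(C:0.1,D:0.1):0.5);")
        aln = _simulate_on_tree(true, 1000, lg, seed=7)
        fit = build_tree(aln, lg, seed=0)
        sup = bootstrap_supports(aln, lg, fit.tree, n_reps=50, seed=2)
        internal = [n.support for n in sup.postorder()
                    if n.support is not None]
        assert len(internal) == 1 and internal[0] >= 0.9

    def test_invariant_to_row_order(self, lg):
        true = parse_newick("((A:0.2,B:0.2):0.3,(C:0.2,D:0.2):0.3);")
        aln = _simulate_on_tree(true, 300, lg, seed=8)
        perm = Alignment({k: aln.rows[k] for k in ["D", "B", "C", "A"]})
        fit = build_tree(aln, lg, seed=0)
        s1 = bootstrap_supports(aln, lg, fit.tree, n_reps=20, seed=3)
        s2 = bootstrap_supports(perm, lg, fit.tree, n_reps=20, seed=3)
        assert s1.support_of_bipartition() == s2.support_of_bipartition()

    def test_zero_replicates_rejected(self, lg):
        aln = Alignment({"A": "MK", "B": "ML", "C": "RK", "D": "RL"})
        fit = build_tree(aln, lg, seed=0)
        with pytest.raises(ValueError):
            bootstrap_supports(aln, lg, fit.tree, n_reps=0, seed=0)


class TestProgressiveAligner:
    def test_lossless_rows(self):
        seqs = [ProteinSequence("a", "MKVLWAAKRE"),
                ProteinSequence("b", "MKVWAAKRE"),
                ProteinSequence("c", "MKVLWAAKE"),
                ProteinSequence("d", "AKVLWGAKRE")]
        aln = progressive_align(seqs)
        for s in seqs:
            assert aln.ungapped(s.id) == s.residues

    def test_identical_sequences_align_without_gaps(self):
        seqs = [ProteinSequence(f"s{i}", "MKVLWAAKRE" * 5) for i in range(4)]
        aln = progressive_align(seqs)
        assert aln.n_cols == 50
        assert len({r for r in aln.rows.values()}) == 1


class TestAdapters:
    """The adapters are exercised against real mafft/fasttree binaries."""

    def test_missing_executable_fails_at_construction(self):
        with pytest.raises(AdapterError, match="not found"):
            ExternalTool("aligner", "no-such-binary-xyz {in} {out}")

    def test_mafft_adapter_lossless(self, lg):
        true = species_tree(4, seed=9)
        aln = _simulate_on_tree(true, 120, lg, seed=9)
        seqs = [ProteinSequence(rid, aln.ungapped(rid))
                for rid in aln.ids()]
        out = mafft_adapter().align(seqs)
        assert set(out.ids()) == {s.id for s in seqs}
        for s in seqs:
            assert out.ungapped(s.id) == s.residues

    def test_fasttree_adapter_leafset_and_supports(self, lg):
        true = species_tree(4, seed=10)
        aln = _simulate_on_tree(true, 200, lg, seed=10)
        tree = fasttree_adapter().build_tree(aln)
        assert set(tree.leaf_names()) == set(aln.ids())
        for n in tree.postorder():
            if n.support is not None:
                assert 0.0 <= n.support <= 1.0
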