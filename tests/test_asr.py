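"""Likelihood machinery and marginal ancestral reconstruction."""

import math

import numpy as np
import pytest

from thermoasr import (
    Alignment,
    SubstitutionModel,
    estimate_alpha,
    marginal_ancestral_profiles,
    optimize_branch_lengths,
    parse_newick,
    simulate_alignment,
    simulate_yule_tree,
    tree_log_likelihood,
)
from thermoasr.errors import IdentityError, TreeError
from thermoasr.models import load_exchangeabilities

from conftest import enum_column_likelihoods, enum_marginal_posterior


@pytest.fixture(scope="module")
def uniform_model():
    R = np.ones((20, 20))
    np.fill_diagonal(R, 0.0)
    return SubstitutionModel(R, np.full(20, 0.05), alpha=1.0, k=1)


class TestTreeLogLikelihood:
    def test_zero_distance_identical_leaves(self, uniform_model):
        tree = parse_newick("(A:0,B:0)R;")
        aln = Alignment(["A", "B"], ["R", "R"])
        ll = tree_log_likelihood(tree, aln, uniform_model)
        assert ll == pytest.approx(math.log(1 / 20), abs=1e-12)

    def test_impossible_data_hits_floor_with_warning(self, uniform_model):
        tree = parse_newick("(A:0,B:0)R;")
        aln = Alignment(["A", "B"], ["R", "K"])
        with pytest.warns(RuntimeWarning, match="zero likelihood"):
            ll = tree_log_likelihood(tree, aln, uniform_model)
        assert ll < -1e9

    def test_matches_enumeration(self, four_leaf_tree, four_leaf_alignment, lg_k2_model):
        ll = tree_log_likelihood(four_leaf_tree, four_leaf_alignment, lg_k2_model)
        oracle = float(np.log(enum_column_likelihoods(
            four_leaf_tree, four_leaf_alignment, lg_k2_model)).sum())
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_unrooted_tree_rejected(self, lg_k2_model):
        tree = parse_newick("(A:1,B:1,C:1);")
        aln = Alignment(["A", "B", "C"], ["R", "K", "D"])
        with pytest.raises(TreeError):
            tree_log_likelihood(tree, aln, lg_k2_model)

    def test_leaf_without_sequence_rejected(self, four_leaf_tree, lg_k2_model):
        aln = Alignment(["A", "B", "C"], ["R", "K", "D"])
        with pytest.raises(IdentityError):
            tree_log_likelihood(four_leaf_tree, aln, lg_k2_model)

    def test_pulley_principle(self):
        # reversible model: likelihood invariant to root position on any branch
        from thermoasr.mad import _branches, _reroot_at, unrooted_view
        from thermoasr import make_ogt_dataset

        tree, aln, _, _ = make_ogt_dataset(n_leaves=8, n_columns=150, seed=11)
        model = SubstitutionModel.from_name("LG", aln, alpha=0.8, k=4)
        ll0 = tree_log_likelihood(tree, aln, model)
        n_branches = len(_branches(unrooted_view(tree)))
        for bid in range(n_branches):
            work = unrooted_view(tree)
            branch = _branches(work)[bid]
            rerooted = _reroot_at(work, branch, branch.length / 2)
            assert tree_log_likelihood(rerooted, aln, model) == pytest.approx(ll0, abs=1e-8)


class TestMarginalProfiles:
    def test_forced_root_state(self, uniform_model):
        tree = parse_newick("(A:0,B:0)R;")
        aln = Alignment(["A", "B"], ["K", "K"])
        profiles = marginal_ancestral_profiles(tree, aln, uniform_model)
        (prof,) = profiles.values()
        k_idx = "ARNDCQEGHILKMFPSTWYV".index("K")
        assert prof.probabilities[0, k_idx] == pytest.approx(1.0)
        assert prof.map_sequence == "K"

    def test_matches_enumeration_everywhere(
        self, four_leaf_tree, four_leaf_alignment, lg_k2_model
    ):
        profiles = marginal_ancestral_profiles(four_leaf_tree, four_leaf_alignment, lg_k2_model)
        for label in ("R", "X", "Y"):
            for col in range(four_leaf_alignment.n_columns):
                oracle = enum_marginal_posterior(
                    four_leaf_tree, four_leaf_alignment, lg_k2_model, label, col
                )
                assert np.abs(profiles[label].probabilities[col] - oracle).max() < 1e-10

    def test_columns_sum_to_one_and_map_attains_max(
        self, four_leaf_tree, four_leaf_alignment, lg_k2_model
    ):
        profiles = marginal_ancestral_profiles(four_leaf_tree, four_leaf_alignment, lg_k2_model)
        for prof in profiles.values():
            sums = prof.probabilities.sum(axis=1)
            assert np.abs(sums - 1.0).max() < 1e-9
            assert np.allclose(prof.map_posterior, prof.probabilities.max(axis=1))

    def test_root_posterior_at_infinite_branches_is_pi(self, lg_k2_model):
        tree = parse_newick("(A:2000,B:2000)R;")
        aln = Alignment(["A", "B"], ["R", "K"])
        profiles = marginal_ancestral_profiles(tree, aln, lg_k2_model)
        (prof,) = profiles.values()
        assert np.abs(prof.probabilities[0] - lg_k2_model.frequencies).max() < 1e-6

    def test_marginal_normalizer_equals_likelihood(
        self, four_leaf_tree, four_leaf_alignment, lg_k2_model
    ):
        from thermoasr.asr import _Engine

        engine = _Engine(four_leaf_tree, four_leaf_alignment, lg_k2_model)
        _, ll_marginal = engine.marginal_profiles()
        ll_direct = tree_log_likelihood(four_leaf_tree, four_leaf_alignment, lg_k2_model)
        assert ll_marginal == pytest.approx(ll_direct, abs=1e-8)

    def test_reconstruction_beats_majority_baseline(self):
        # simulated under the shipped LG model: mean posterior of the true
        # root residue must exceed the most common residue's frequency
        tree = simulate_yule_tree(12, 0.2, seed=41)
        R, pi = load_exchangeabilities("LG")
        freqs = {n.label: pi for n in tree.preorder()}
        aln, truth = simulate_alignment(tree, freqs, 400, R, alpha=1.0, k=1, seed=42)
        root_states = np.array(
            ["ARNDCQEGHILKMFPSTWYV".index(c) for c in truth.node_sequences[tree.root.label]]
        )
        model = SubstitutionModel(R, pi, alpha=1.0, k=1)
        profiles = marginal_ancestral_profiles(tree, aln, model)
        root_prof = profiles[tree.root.label]
        mean_true_post = float(root_prof.probabilities[np.arange(400), root_states].mean())
        assert mean_true_post > float(pi.max())


class TestEstimateAlpha:
    def test_recovers_simulated_shape(self):
        tree = simulate_yule_tree(16, 0.3, seed=21)
        R, pi = load_exchangeabilities("LG")
        freqs = {n.label: pi for n in tree.preorder()}
        aln, _ = simulate_alignment(tree, freqs, 2000, R, alpha=0.7, k=4, seed=22)
        model = SubstitutionModel.from_name("LG", aln, alpha=1.0, k=4)
        est = estimate_alpha(tree, aln, model)
        assert abs(est.alpha - 0.7) < 0.2
        assert not est.at_boundary
        # returned likelihood is a maximum: no worse than at alpha = 1
        assert est.log_likelihood >= tree_log_likelihood(tree, aln, model) - 1e-9

    def test_constant_rate_data_hits_upper_boundary(self):
        tree = simulate_yule_tree(8, 0.3, seed=23)
        R, pi = load_exchangeabilities("LG")
        freqs = {n.label: pi for n in tree.preorder()}
        aln, _ = simulate_alignment(tree, freqs, 500, R, alpha=1.0, k=1, seed=24)
        model = SubstitutionModel.from_name("LG", aln, alpha=1.0, k=4)
        with pytest.warns(RuntimeWarning, match="boundary"):
            est = estimate_alpha(tree, aln, model, bounds=(0.02, 20.0))
        assert est.at_boundary
        assert est.alpha > 10.0


class TestOptimizeBranchLengths:
    def test_recovers_simulated_lengths(self):
        # root-adjacent edges are unidentifiable individually (pulley
        # principle); assert them as a sum, everything else relatively
        true = parse_newick("((A:0.1,B:0.6)X:0.25,(C:0.05,(D:0.4,E:0.9)Y:0.3)Z:0.8)R;")
        R, pi = load_exchangeabilities("LG")
        freqs = {n.label: pi for n in true.preorder()}
        aln, _ = simulate_alignment(true, freqs, 5000, R, alpha=1.0, k=1, seed=31)
        start = true.copy()
        for node in start.preorder():
            if node is not start.root:
                node.length = 0.3
        model = SubstitutionModel(R, pi, alpha=1.0, k=1)
        fitted, ll = optimize_branch_lengths(start, aln, model)
        true_len = {n.label: n.length for n in true.preorder() if n is not true.root}
        fit_len = {n.label: n.length for n in fitted.preorder() if n is not fitted.root}
        root_pair = {c.label for c in true.root.children}
        for label, tv in true_len.items():
            if label in root_pair:
                continue
            assert abs(fit_len[label] - tv) / tv < 0.15, label
        true_sum = sum(true_len[l] for l in root_pair)
        fit_sum = sum(fit_len[l] for l in root_pair)
        assert abs(fit_sum - true_sum) / true_sum < 0.15
        assert ll >= tree_log_likelihood(start, aln, model)

    def test_optimal_input_is_fixed_point(self):
        true = parse_newick("((A:0.2,B:0.3)X:0.2,(C:0.25,D:0.15)Y:0.2)R;")
        R, pi = load_exchangeabilities("LG")
        freqs = {n.label: pi for n in true.preorder()}
        aln, _ = simulate_alignment(true, freqs, 1500, R, alpha=1.0, k=1, seed=33)
        model = SubstitutionModel(R, pi, alpha=1.0, k=1)
        once, _ = optimize_branch_lengths(true, aln, model)
        twice, _ = optimize_branch_lengths(once, aln, model)
        for n1, n2 in zip(once.preorder(), twice.preorder()):
            if n1.length is not None:
                assert abs(n1.length - n2.length) < 1e-3

    def test_zero_branch_with_identical_flanks_stays_zero(self):
        tree = parse_newick("((A:0.0,B:0.0)X:0.2,C:0.3)R;")
        aln = Alignment(["A", "B", "C"], ["RKDE" * 25, "RKDE" * 25, "QNST" * 25])
        R, pi = load_exchangeabilities("LG")
        model = SubstitutionModel(R, pi, alpha=1.0, k=1)
        fitted, _ = optimize_branch_lengths(tree, aln, model)
        for leaf in fitted.leaves():
            if leaf.label in ("A", "B"):
                assert leaf.length < 1e-3
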