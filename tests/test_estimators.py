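"""The four species-tree estimation methods."""

import math
import warnings

import numpy as np
import pytest

import coaltrio as ct
from coaltrio.estimators import EstimationError


def dataset(rows, n):
    return ct.MultilocusDataset(n=n, counts=np.array(rows))


def loci_from_patterns(site_patterns):
    """Build n=2 loci from two-character pattern strings like '11', '02'."""
    rows = []
    for s in site_patterns:
        x = np.zeros(5, dtype=int)
        for ch in s:
            x[int(ch)] += 1
        rows.append(x)
    return dataset(rows, len(site_patterns[0]))


class TestMlGeneTree:
    def test_strict_argmax(self):
        assert ct.ml_gene_tree(np.array([0, 5, 3, 2, 0])).winner == 1

    def test_tie(self):
        call = ct.ml_gene_tree(np.array([0, 4, 4, 1, 1]))
        assert call.winner is None
        assert call.tie == (1, 2)

    def test_all_constant_three_way_tie(self):
        assert ct.ml_gene_tree(np.array([9, 0, 0, 0, 0])).tie == (1, 2, 3)

    def test_count_rule_is_ml(self, std_params):
        """The informative-count argmax maximizes the JC-clock likelihood
        over the three gene trees (grid-search oracle)."""
        rng = np.random.default_rng(31)
        t1g = np.linspace(1e-4, 0.2, 40)
        checked = 0
        for _ in range(100):
            x = ct.simulate.sample_counts(std_params, 1, 60, rng)[0]
            call = ct.ml_gene_tree(x)
            if call.winner is None:
                continue
            best = []
            for perm in [(0, 1, 2, 3, 4), (0, 2, 1, 3, 4), (0, 3, 2, 1, 4)]:
                xp = x[list(perm)]
                ll = -np.inf
                for t1 in t1g:
                    for dt in np.linspace(0, 0.2, 40):
                        p = ct.conditional_pattern_probs(t1 + dt, t1)
                        with np.errstate(divide="ignore"):
                            ll = max(ll, float(xp @ np.log(p)))
                best.append(ll)
            if np.isclose(max(best), sorted(best)[-2], atol=1e-9):
                continue  # oracle tie, rule tie-handling not comparable
            assert int(np.argmax(best)) + 1 == call.winner
            checked += 1
        assert checked >= 50


class TestTwoStep:
    def test_tie_example(self):
        """Loci '11','02','00' split the vote between S1 and S2."""
        data = loci_from_patterns(["11", "02", "00"])
        call = ct.two_step(data, tie_policy="drop")
        assert call.winner is None
        assert call.tie == (1, 2)
        np.testing.assert_allclose(call.support, [1, 1, 0])
        call_even = ct.two_step(data, tie_policy="even")
        assert call_even.tie == (1, 2)

    def test_correct_call_example(self):
        """Loci '33','01','14' give votes (2, 0, 1) and the right tree."""
        call = ct.two_step(loci_from_patterns(["33", "01", "14"]))
        assert call.winner == 1
        np.testing.assert_allclose(call.support, [2, 0, 1])

    def test_pure_informative(self):
        data = dataset([[0, 3, 0, 0, 0]] * 5, 3)
        assert ct.two_step(data).winner == 1

    def test_random_policy_seeded(self):
        data = loci_from_patterns(["11", "02", "00"])
        a = ct.two_step(data, tie_policy="random", rng=np.random.default_rng(1))
        b = ct.two_step(data, tie_policy="random", rng=np.random.default_rng(1))
        np.testing.assert_array_equal(a.support, b.support)

    def test_infinite_sites_uses_true_topology(self, std_params):
        data = ct.sample_dataset(std_params, 2000, math.inf, seed=77)
        call = ct.two_step(data)
        # votes match the per-locus argmax of exact pattern probabilities
        winners = np.argmax(data.probs[:, 1:4], axis=1)
        np.testing.assert_allclose(call.support, np.bincount(winners, minlength=3))


class TestConcatIsmlTopology:
    def test_correct_call_example(self):
        call = ct.concat_isml_topology(loci_from_patterns(["11", "02", "00"]))
        assert call.winner == 1
        np.testing.assert_allclose(call.support, [2, 1, 0])

    def test_tie_example(self):
        call = ct.concat_isml_topology(loci_from_patterns(["33", "01", "14"]))
        assert call.winner is None
        assert call.tie == (1, 3)
        np.testing.assert_allclose(call.support, [2, 0, 2])

    def test_all_constant_three_way_tie(self):
        call = ct.concat_isml_topology(dataset([[4, 0, 0, 0, 0]] * 3, 4))
        assert call.tie == (1, 2, 3)


class TestConcatFitTimes:
    def test_self_consistency_at_truth(self):
        p = ct.conditional_pattern_probs(0.03, 0.02)
        fit = ct.concat_fit_times(p * 1e7)
        assert fit.t0_hat == pytest.approx(0.03, abs=1e-8)
        assert fit.t1_hat == pytest.approx(0.02, abs=1e-8)

    def test_degenerate_counts(self):
        with pytest.warns(UserWarning):
            fit = ct.concat_fit_times(np.array([100.0, 0, 0, 0, 0]))
        assert fit.boundary
        assert fit.t0_hat == fit.t1_hat == 0.0

    def test_pseudotrue_fit_matches_grid_oracle(self, deep_params):
        """Fitting the conditional pattern model to the exact marginal
        (the m -> infinity limit) agrees with a fine-grid KL minimizer."""
        pbar = ct.marginal_pattern_probs(deep_params).pbar
        fit = ct.concat_fit_times(pbar)
        # coarse-to-fine grid oracle
        best = (None, -np.inf)
        t1_grid = np.linspace(0.005, 0.04, 120)
        for t1 in t1_grid:
            for dt in np.linspace(0.0, 0.04, 120):
                ll = float(pbar @ np.log(ct.conditional_pattern_probs(t1 + dt, t1)))
                if ll > best[1]:
                    best = ((t1 + dt, t1), ll)
        (t0g, t1g), _ = best
        for _ in range(3):
            t0s = np.linspace(t0g - 3e-4, t0g + 3e-4, 41)
            t1s = np.linspace(t1g - 3e-4, t1g + 3e-4, 41)
            best = (None, -np.inf)
            for t1 in t1s:
                for t0 in t0s[t0s >= t1]:
                    ll = float(pbar @ np.log(ct.conditional_pattern_probs(t0, t1)))
                    if ll > best[1]:
                        best = ((t0, t1), ll)
            (t0g, t1g), _ = best
        assert fit.t0_hat == pytest.approx(t0g, abs=1e-5)
        assert fit.t1_hat == pytest.approx(t1g, abs=1e-5)
        # the documented bias: pseudotrue ages differ sharply from the taus
        assert abs(fit.t0_hat - deep_params.tau0) > 0.005


class TestIsmlEstimateParams:
    def test_forward_inverse_round_trip(self):
        pbar = ct.marginal_pattern_probs_equal_theta(0.02, 0.01, 0.02).pbar
        est = ct.isml_estimate_params(pbar)
        assert est.tau0_hat == pytest.approx(0.02, abs=1e-10)
        assert est.tau1_hat == pytest.approx(0.01, abs=1e-10)
        assert est.theta_hat == pytest.approx(0.02, abs=1e-10)

    def test_saturation_failure(self):
        uniform = np.array([1, 3, 3, 3, 6]) / 16.0
        with pytest.raises(EstimationError):
            ct.isml_estimate_params(uniform)

    def test_unequal_theta_inconsistency(self, std_params):
        """With theta0 != theta1 truth the equal-theta inversion returns
        finite estimates that are NOT the true parameters."""
        pbar = ct.marginal_pattern_probs(std_params).pbar
        est = ct.isml_estimate_params(pbar)
        assert est.theta_hat > 0
        assert est.tau0_hat > est.tau1_hat > 0
        truth = np.array([std_params.tau0, std_params.tau1])
        fitted = np.array([est.tau0_hat, est.tau1_hat])
        assert not np.allclose(fitted, truth, rtol=0.02)


class TestMscLoglik:
    def test_single_site_equals_marginal(self, std_params):
        pbar = ct.marginal_pattern_probs(std_params).pbar
        for j in range(5):
            x = np.zeros(5, dtype=int)
            x[j] = 1
            assert ct.msc_loglik(x, 1, std_params) == pytest.approx(
                math.log(pbar[j]), abs=1e-10
            )

    def test_empty_dataset(self, std_params):
        assert ct.msc_loglik(np.zeros((0, 5), dtype=int), 1, std_params) == 0.0

    @pytest.mark.parametrize(
        "x", [[3, 2, 1, 1, 3], [40, 4, 3, 2, 1], [230, 9, 5, 4, 2]],
        ids=["small", "n50", "n250"],
    )
    def test_against_adaptive_oracle(self, std_params, adaptive_loglik_oracle, x):
        x = np.array(x)
        mine = ct.msc_loglik(x, 1, std_params)
        oracle = adaptive_loglik_oracle(x, std_params, scale_hint=mine)
        assert abs(mine - oracle) < 1e-8 * abs(oracle)

    def test_quadrature_self_convergence(self, std_params):
        x = np.array([230, 9, 5, 4, 2])
        a = ct.msc_loglik(x, 1, std_params, quad_nodes=16)
        b = ct.msc_loglik(x, 1, std_params, quad_nodes=64)
        assert a == pytest.approx(b, abs=1e-9)

    def test_species_relabelling_symmetry(self, std_params):
        """Swapping species A and B permutes counts (x2 <-> x3) and maps
        the S2 likelihood onto S3 while preserving S1."""
        x = np.array([[10, 4, 3, 2, 1]])
        xs = x[:, [0, 1, 3, 2, 4]]
        assert ct.msc_loglik(xs, 1, std_params) == pytest.approx(
            ct.msc_loglik(x, 1, std_params), abs=1e-12
        )
        assert ct.msc_loglik(xs, 2, std_params) == pytest.approx(
            ct.msc_loglik(x, 3, std_params), abs=1e-12
        )

    def test_per_locus_sums_to_total(self, std_params):
        data = ct.sample_dataset(std_params, 50, 10, seed=41)
        per = ct.msc_loglik(data, 2, std_params, per_locus=True)
        assert per.sum() == pytest.approx(
            ct.msc_loglik(data, 2, std_params), rel=1e-12
        )


class TestMlFit:
    def test_single_locus_matches_gene_tree(self, std_params):
        """With one locus the ML species tree is the ML gene tree for
        ordinary data."""
        rng = np.random.default_rng(51)
        tried = 0
        while tried < 3:
            x = ct.simulate.sample_counts(std_params, 1, 80, rng)
            gcall = ct.ml_gene_tree(x[0])
            if gcall.winner is None or sorted(x[0][1:4])[-1] - sorted(x[0][1:4])[-2] < 2:
                continue
            scall = ct.ml_msc_species_tree(
                ct.MultilocusDataset(n=80, counts=x), n_starts=1, quad_nodes=16
            )
            assert scall.winner == gcall.winner
            tried += 1

    def test_identifiability_warning_at_n1(self, std_params):
        data = ct.sample_dataset(std_params, 30, 1, seed=52)
        with pytest.warns(UserWarning, match="identifiable"):
            ct.ml_msc_fit(data, 1, n_starts=1, quad_nodes=16)

    def test_deterministic(self, deep_params):
        data = ct.sample_dataset(deep_params, 100, 20, seed=53)
        a = ct.ml_msc_fit(data, 1, n_starts=2, quad_nodes=16)
        b = ct.ml_msc_fit(data, 1, n_starts=2, quad_nodes=16)
        assert a.loglik == b.loglik
        assert a.params_hat == b.params_hat


class TestInfiniteSitesRule:
    def test_g1a_locus_forces_s1(self, std_params):
        gts = [
            ct.GeneTreeSample("G1a", t1=0.0195, t0=0.025),
            ct.GeneTreeSample("G2", t1=0.03, t0=0.05),
        ]
        call = ct.species_tree_from_true_gene_trees(gts)
        assert call.winner == 1

    def test_error_matches_exact_formula(self, std_params):
        """Error frequency of the minimum-time rule matches phi^m 2/3."""
        for m in (1, 5, 20):
            est = ct.run_error_experiment(
                "ml", std_params, m=m, n=math.inf, R=40_000, seed=m
            )
            exact = ct.ml_error_infinite_n(std_params, m).value
            assert abs(est.error - exact) < 3 * max(est.mc_se, 1e-4)


class TestPooledArgmaxOptimality:
    def test_pooled_argmax_equals_maximized_likelihood(self, pooled_ml_oracle):
        """The pooled-count argmax call coincides with the argmax of the
        maximized pooled-pattern likelihoods over the full parameter
        space (direct-optimization oracle), on random small datasets."""
        rng = np.random.default_rng(61)
        params_pool = [
            ct.SpeciesTreeParams(0.02, 0.019, 0.01, 0.05),
            ct.SpeciesTreeParams(0.02, 0.01, 0.02, 0.01),
            ct.SpeciesTreeParams(0.05, 0.02, 0.05, 0.1),
        ]
        checked = 0
        attempts = 0
        while checked < 50 and attempts < 400:
            attempts += 1
            p = params_pool[rng.integers(len(params_pool))]
            m = int(rng.integers(1, 6))
            n = int(rng.integers(1, 7))
            counts = ct.simulate.sample_counts(p, m, n, rng)
            pooled = counts.sum(axis=0)
            stats = pooled[1:4]
            top = np.sort(stats)[-1]
            if (stats == top).sum() > 1:
                continue  # ties: argmax and likelihood both tie, skip
            winner = int(np.argmax(stats)) + 1
            lls = pooled_ml_oracle(pooled)
            assert int(np.argmax(lls)) + 1 == winner, (pooled, lls)
            checked += 1
        assert checked == 50
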