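"""Resampling statistics: permutation tests, FDR, bootstrap, hierarchy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from midvision.inference import (
    bootstrap_ci_mean,
    bootstrap_peak_ci,
    bootstrap_peak_difference,
    condition_swap_test,
    fdr_bh,
    hierarchy_correlation,
    peak_location,
    sign_permutation_test,
)


class TestSignPermutation:
    def test_all_subjects_at_chance_gives_p_one(self):
        vals = np.full((8, 3), 50.0)
        res = sign_permutation_test(vals, n_perm=500, chance=50.0, seed=1)
        assert np.all(res.p_raw == 1.0)

    def test_strong_consistent_effect_reaches_minimum_p(self):
        vals = 10.0 + 0.01 * np.random.default_rng(0).standard_normal((25, 2))
        res = sign_permutation_test(vals, n_perm=1000, chance=0.0, seed=2)
        assert np.all(res.p_raw == pytest.approx(1 / 1001))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            sign_permutation_test(np.zeros((1, 4)))

    def test_adjusted_p_at_least_raw(self, rng):
        vals = rng.standard_normal((10, 20)) + 0.3
        res = sign_permutation_test(vals, n_perm=500, seed=3)
        assert np.all(res.p_adjusted >= res.p_raw - 1e-12)
        assert np.array_equal(res.significant, res.p_adjusted <= res.alpha)


class TestConditionSwap:
    def test_identical_groups_not_significant(self):
        a = np.tile(np.arange(5.0), (6, 1))
        res = condition_swap_test(a, a.copy(), n_perm=500, seed=1)
        assert np.all(res.p_raw > 0.9)

    def test_hugely_separated_groups_reach_minimum_p(self, rng):
        a = rng.standard_normal((10, 2))
        b = rng.standard_normal((12, 2)) + 50.0
        res = condition_swap_test(a, b, n_perm=1000, seed=2)
        assert np.all(res.p_raw < 0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            condition_swap_test(np.zeros((0, 3)), np.zeros((4, 3)))


def _bh_oracle(p, alpha):
    """Literal step-up definition: reject 1..k where k = max{i: p_(i) <= i a/m}."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    adjusted = np.empty(m)
    running = 1.0
    for i in range(m, 0, -1):
        running = min(running, p[order[i - 1]] * m / i)
        adjusted[order[i - 1]] = running
    return adjusted, reject


class TestFdrBH:
    def test_worked_example_all_rejected(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        _, reject = fdr_bh(p, alpha=0.05)
        assert reject.all()  # p_(i) <= i*alpha/m holds at i = m

    def test_all_ones_none_rejected(self):
        adj, reject = fdr_bh(np.ones(7))
        assert not reject.any() and np.all(adj == 1.0)

    def test_single_p_adjusted_equals_raw(self):
        adj, _ = fdr_bh(np.array([0.031]))
        assert adj[0] == pytest.approx(0.031)

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=12),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_matches_brute_force_step_up_oracle(self, p, alpha):
        p = np.asarray(p)
        adj, reject = fdr_bh(p, alpha=alpha)
        adj_o, reject_o = _bh_oracle(p, alpha)
        assert np.allclose(adj, np.minimum(adj_o, 1.0))
        assert np.array_equal(reject, reject_o)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([-0.1]))


class TestBootstrapMean:
    def test_identical_values_give_degenerate_interval(self):
        lo, hi = bootstrap_ci_mean(np.full(10, 3.5), n_boot=200, seed=1)
        assert lo == hi == 3.5

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(7)
        covered = 0
        n_rep = 300
        for i in range(n_rep):
            lo, hi = bootstrap_ci_mean(rng.standard_normal(20), n_boot=400, seed=i)
            covered += lo <= 0 <= hi
        assert 0.90 <= covered / n_rep <= 0.98

    def test_interval_narrows_with_sample_size(self):
        rng = np.random.default_rng(8)
        pop = rng.standard_normal(1000)
        lo5, hi5 = bootstrap_ci_mean(pop[:5], n_boot=2000, seed=1)
        lo50, hi50 = bootstrap_ci_mean(pop[:50], n_boot=2000, seed=1)
        assert (hi50 - lo50) < (hi5 - lo5)

    def test_affine_equivariance(self, rng):
        vals = rng.standard_normal(15)
        lo, hi = bootstrap_ci_mean(vals, n_boot=1000, seed=4)
        lo2, hi2 = bootstrap_ci_mean(3 * vals + 7, n_boot=1000, seed=4)
        assert lo2 == pytest.approx(3 * lo + 7) and hi2 == pytest.approx(3 * hi + 7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci_mean(np.array([]))


class TestPeaks:
    def test_peak_index_maps_to_grid_value(self):
        grid = -400 + 20 * np.arange(70)
        curve = np.zeros(70)
        curve[5] = 1.0
        assert peak_location(curve, grid) == -300.0

    def test_constant_curve_takes_first_grid_point(self):
        assert peak_location(np.ones(10), np.arange(10) * 2.0) == 0.0

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            peak_location(np.full(5, np.nan), np.arange(5.0))

    def test_shared_sharp_peak_gives_zero_width_ci(self):
        grid = np.arange(20.0)
        curve = np.exp(-((grid - 7) ** 2))
        curves = np.tile(curve, (6, 1))
        est = bootstrap_peak_ci(curves, grid, n_boot=500, seed=1)
        assert est.peak == 7.0 and est.ci == (7.0, 7.0)

    def test_planted_peak_difference_detected(self, rng):
        grid = np.arange(0, 400, 20.0)
        t = grid[None, :]
        a = np.exp(-((t - 100) ** 2) / 800) + 0.02 * rng.standard_normal((10, len(grid)))
        b = np.exp(-((t - 200) ** 2) / 800) + 0.02 * rng.standard_normal((10, len(grid)))
        diff, (lo, hi) = bootstrap_peak_difference(b, a, grid, n_boot=1000, seed=2)
        assert diff == pytest.approx(100.0, abs=20)
        assert lo > 0  # CI excludes zero

    def test_same_condition_difference_ci_contains_zero(self, rng):
        grid = np.arange(0, 400, 20.0)
        curves = np.exp(-((grid[None] - 150) ** 2) / 2000) + 0.1 * rng.standard_normal(
            (8, len(grid))
        )
        _, (lo, hi) = bootstrap_peak_difference(curves, curves, grid, n_boot=800, seed=3)
        assert lo <= 0 <= hi


class TestHierarchy:
    def test_identical_ranking_seven_features(self):
        res = hierarchy_correlation(np.arange(7.0), np.arange(7.0) * 3 + 1)
        assert res.r_s == pytest.approx(1.0)
        assert res.n_permutations == 5040
        assert res.p_value == pytest.approx(1 / 5040)
        assert res.exhaustive

    def test_reversed_ranking_antitone(self):
        res = hierarchy_correlation(np.arange(7.0), np.arange(7.0)[::-1])
        assert res.r_s == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_scipy_spearman_with_ties(self, rng):
        lat = rng.standard_normal(7)
        lay = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        res = hierarchy_correlation(lat, lay)
        assert res.r_s == pytest.approx(spearmanr(lat, lay).statistic)

    def test_exhaustive_matches_monte_carlo(self, rng):
        lat, lay = rng.standard_normal(6), rng.standard_normal(6)
        exact = hierarchy_correlation(lat, lay)
        null = [
            spearmanr(lat, rng.permutation(lay)).statistic for _ in range(20000)
        ]
        mc_p = np.mean(np.asarray(null) >= exact.r_s - 1e-12)
        se = np.sqrt(mc_p * (1 - mc_p) / 20000)
        assert abs(exact.p_value - mc_p) < 3 * se + 1e-3

    def test_monte_carlo_fallback_above_enumeration_cap(self, rng):
        res = hierarchy_correlation(
            rng.standard_normal(9), rng.standard_normal(9), n_mc=2000
        )
        assert not res.exhaustive and res.n_permutations == 2000

    def test_length_mismatch_and_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            hierarchy_correlation(np.arange(5.0), np.arange(4.0))
        with pytest.raises(ValueError):
            hierarchy_correlation(np.arange(2.0), np.arange(2.0))


class TestCalibration:
    """Type-I error of the permutation tests under simulated nulls."""

    def test_sign_test_rejects_at_alpha(self):
        rng = np.random.default_rng(11)
        rej = sum(
            sign_permutation_test(
                rng.standard_normal((12, 1)), n_perm=400, seed=i
            ).p_raw[0]
            <= 0.05
            for i in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08

    def test_swap_test_rejects_at_alpha(self):
        rng = np.random.default_rng(13)
        rej = sum(
            condition_swap_test(
                rng.standard_normal((8, 1)), rng.standard_normal((10, 1)),
                n_perm=400, seed=i,
            ).p_raw[0]
            <= 0.05
            for i in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08

    def test_hierarchy_test_valid_under_null(self):
        rng = np.random.default_rng(17)
        rej = sum(
            hierarchy_correlation(
                rng.standard_normal(5), rng.standard_normal(5)
            ).p_value
            <= 0.05
            for _ in range(400)
        )
        assert rej / 400 <= 0.08
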