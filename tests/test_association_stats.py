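"""Welch tests, cluster-robust OLS, chi-square, Katz RR, Cornfield OR."""

import math

import numpy as np
import pytest
from scipy import stats

from egosupport.association_stats import (TwoByTwoTable, cluster_robust_ols,
                                          odds_ratio_cornfield,
                                          pearson_chi_square, risk_ratio_katz,
                                          welch_from_summary, welch_t_test)

PANEL_A = TwoByTwoTable(64, 2, 21, 13)
PANEL_B = TwoByTwoTable(51, 1, 34, 14)


class TestWelch:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = welch_t_test(x, x)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_printed_summary_row(self):
        # material support by ego gender: 8.8 (SE 1.4, n 68) vs 1.8 (SE 0.75, n 32)
        res = welch_from_summary(8.8, 1.4, 68, 1.8, 0.75, 32)
        assert res.statistic == pytest.approx(4.41, abs=0.005)
        assert res.p_value < 1e-4

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        r1, r2 = welch_t_test(x, y), welch_t_test(y, x)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 25), rng.normal(0.3, 1.7, 40)
        ours = welch_t_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_degenerate_zero_se(self):
        with pytest.raises(ValueError, match="degenerate|zero"):
            welch_from_summary(1.0, 0.0, 10, 1.0, 0.0, 10)


class TestClusterRobustOls:
    def test_singleton_clusters_reduce_to_hc1(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(11)
        n = 60
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(size=n) * (1 + np.abs(x))
        res = cluster_robust_ols(y, x, cluster=np.arange(n))
        ref = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC1")
        assert res[0].estimate == pytest.approx(ref.params[0])
        assert res[1].estimate == pytest.approx(ref.params[1])
        ours_se = (res[1].ci_upper - res[1].ci_lower) / (
            2 * stats.t.ppf(0.975, n - 1))
        assert ours_se == pytest.approx(ref.bse[1], rel=1e-10)

    def test_matches_statsmodels_cluster_covariance(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        g = np.repeat(np.arange(25), 4)
        x = rng.normal(size=100)
        y = 0.5 + 1.5 * x + rng.normal(size=25).repeat(4) + rng.normal(size=100)
        res = cluster_robust_ols(y, x, cluster=g)
        ref = sm.OLS(y, sm.add_constant(x)).fit(
            cov_type="cluster", cov_kwds={"groups": g}, use_t=True)
        assert res[1].estimate == pytest.approx(ref.params[1])
        ours_se = (res[1].ci_upper - res[1].ci_lower) / (
            2 * stats.t.ppf(0.975, 24))
        assert ours_se == pytest.approx(ref.bse[1], rel=1e-8)
        assert res[1].p_value == pytest.approx(ref.pvalues[1], rel=1e-6)

    def test_binary_predictor_slope_is_mean_difference(self):
        y = np.array([1.0, 3.0, 2.0, 8.0, 6.0, 10.0])
        x = np.array([0, 0, 0, 1, 1, 1])
        res = cluster_robust_ols(y, x, cluster=np.arange(6))
        assert res[1].estimate == pytest.approx(8.0 - 2.0)

    def test_robust_se_exceeds_classical_under_clustering(self):
        """With cluster-correlated errors the sandwich SE is larger than the
        classical OLS SE on average (Monte Carlo)."""
        import statsmodels.api as sm
        rng = np.random.default_rng(13)
        wins = 0
        reps = 200
        for _ in range(reps):
            g = np.repeat(np.arange(20), 5)
            x = rng.normal(size=20).repeat(5)  # cluster-constant predictor
            y = x + 2.0 * rng.normal(size=20).repeat(5) + rng.normal(size=100)
            res = cluster_robust_ols(y, x, cluster=g)
            robust_se = (res[1].ci_upper - res[1].ci_lower) / (
                2 * stats.t.ppf(0.975, 19))
            classical = sm.OLS(y, sm.add_constant(x)).fit().bse[1]
            wins += robust_se > classical
        assert wins / reps > 0.8

    def test_single_cluster_and_collinearity_rejected(self):
        y = np.arange(6.0)
        with pytest.raises(ValueError, match="cluster"):
            cluster_robust_ols(y, np.arange(6.0), cluster=np.zeros(6))
        X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="collinear"):
            cluster_robust_ols(y, X, cluster=np.arange(6), names=["a", "b"])


class TestChiSquare:
    def test_perfect_independence(self):
        res = pearson_chi_square([[10, 10], [10, 10]], fisher_fallback=False)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_equals_n(self):
        res = pearson_chi_square([[20, 0], [0, 20]], fisher_fallback=False)
        assert res.statistic == pytest.approx(40.0)
        assert res.p_value < 1e-3

    def test_invariant_under_permutation(self):
        t = np.array([[12, 5], [7, 20]])
        base = pearson_chi_square(t, fisher_fallback=False)
        for perm in (t[::-1], t[:, ::-1], t.T):
            res = pearson_chi_square(perm, fisher_fallback=False)
            assert res.statistic == pytest.approx(base.statistic)

    def test_fisher_fallback_on_sparse_2x2(self):
        res = pearson_chi_square([[2, 1], [1, 3]], fisher_fallback=True)
        assert res.method == "fisher_exact"
        ref = stats.fisher_exact([[2, 1], [1, 3]])[1]
        assert res.p_value == pytest.approx(ref)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            pearson_chi_square([[0, 0], [0, 0]])


class TestKatzRiskRatio:
    @pytest.mark.parametrize("table, rr, lo, hi", [
        (PANEL_B, 1.38, 1.15, 1.67),
        (PANEL_A, 1.57, 1.20, 2.05),
    ])
    def test_published_panels(self, table, rr, lo, hi):
        res = risk_ratio_katz(table)
        assert round(res.estimate, 2) == rr
        assert round(res.ci_lower, 2) == lo
        assert round(res.ci_upper, 2) == hi

    def test_equal_risks_give_unity(self):
        res = risk_ratio_katz(TwoByTwoTable(10, 10, 20, 20))
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_lower < 1.0 < res.ci_upper

    def test_interval_contains_point_and_narrows_with_n(self):
        small = risk_ratio_katz(TwoByTwoTable(8, 2, 5, 5))
        big = risk_ratio_katz(TwoByTwoTable(80, 20, 50, 50))
        for res in (small, big):
            assert res.ci_lower <= res.estimate <= res.ci_upper
        assert (big.ci_upper - big.ci_lower) < (small.ci_upper - small.ci_lower)

    def test_zero_cell_flags(self):
        inf_res = risk_ratio_katz(TwoByTwoTable(5, 5, 0, 10))
        assert math.isinf(inf_res.estimate)
        zero_res = risk_ratio_katz(TwoByTwoTable(0, 10, 5, 5))
        assert zero_res.estimate == 0.0
        assert zero_res.ci_upper > 0


class TestCornfieldOddsRatio:
    def test_published_panels(self):
        a = odds_ratio_cornfield(PANEL_A)
        assert a.estimate == pytest.approx(64 * 13 / (2 * 21))
        assert round(a.ci_lower, 2) == 4.54
        assert a.upper_unbounded
        b = odds_ratio_cornfield(PANEL_B)
        assert round(b.estimate, 2) == 21.00
        assert round(b.ci_lower, 2) == 3.33
        assert b.upper_unbounded

    def test_cross_product_unity(self):
        res = odds_ratio_cornfield(TwoByTwoTable(10, 20, 5, 10))
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_lower < 1.0 < res.ci_upper

    def test_lower_limit_matches_independent_root(self):
        """Cross-check the iterative solver against a brentq root of the
        independently written interval equation."""
        from scipy.optimize import brentq
        z = stats.norm.ppf(0.975)
        for t in (PANEL_A, PANEL_B, TwoByTwoTable(30, 10, 15, 25),
                  TwoByTwoTable(12, 8, 9, 11)):
            def f(A):
                B, C, D = t.n1 - A, t.m1 - A, t.m0 - t.n1 + A
                V = 1.0 / (1 / A + 1 / B + 1 / C + 1 / D)
                return t.a - A - z * math.sqrt(V)
            lo = max(0.0, t.n1 - t.m0) + 1e-9
            A = brentq(f, lo, t.a - 1e-12, xtol=1e-12)
            B, C, D = t.n1 - A, t.m1 - A, t.m0 - t.n1 + A
            expected = A * D / (B * C)
            res = odds_ratio_cornfield(t)
            assert res.ci_lower == pytest.approx(expected, rel=1e-5)

    def test_limits_monotone_in_alpha(self):
        t = TwoByTwoTable(30, 10, 15, 25)
        narrow = odds_ratio_cornfield(t, alpha=0.10)
        wide = odds_ratio_cornfield(t, alpha=0.01)
        assert wide.ci_lower < narrow.ci_lower < t.a * t.d / (t.b * t.c)
        assert wide.ci_upper > narrow.ci_upper

    def test_moderate_table_has_finite_upper(self):
        res = odds_ratio_cornfield(TwoByTwoTable(30, 10, 15, 25))
        assert not res.upper_unbounded
        assert res.ci_lower < res.estimate < res.ci_upper

    def test_continuity_correction_widens_interval(self):
        t = TwoByTwoTable(30, 10, 15, 25)
        plain = odds_ratio_cornfield(t)
        corrected = odds_ratio_cornfield(t, continuity_correction=0.5)
        assert corrected.ci_lower < plain.ci_lower

    def test_zero_cell_infinite_estimate(self):
        res = odds_ratio_cornfield(TwoByTwoTable(10, 0, 5, 10))
        assert math.isinf(res.estimate)
        assert res.upper_unbounded
        assert res.ci_lower > 1.0

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(-1, 2, 3, 4)
        with pytest.raises(ValueError, match="margins"):
            odds_ratio_cornfield(TwoByTwoTable(0, 0, 5, 5))
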