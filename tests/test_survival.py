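"""Survival statistics against independent oracles.

Kaplan–Meier and the log-rank test are cross-checked against lifelines; the
Cox coefficient against a grid-maximized explicit partial likelihood; the
Youden cutoff against exhaustive threshold search; AUC against the
Mann–Whitney U identity; Spearman against Pearson on mid-ranks.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lesionkit as lk
from lesionkit.survival import cox_fit, km_estimate, logrank_test, roc_youden, spearman


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(curve.survival_prob, [0.75, 0.5, 0.25, 0.0])
        assert curve.median == 2.0

    def test_all_censored_curve_is_one_median_undefined(self):
        curve = km_estimate([5, 10, 15], [0, 0, 0])
        assert curve.event_times.size == 0
        assert np.isnan(curve.median)

    def test_mixed_censoring_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        t = rng.exponential(100, 40).round()
        e = rng.random(40) < 0.6
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tj, sj in zip(curve.event_times, curve.survival_prob):
            assert sj == pytest.approx(float(kmf.predict(tj)), abs=1e-10)

    def test_hand_computed_product_limit_n8(self):
        # t:      1+  2   2   3+  5   6+  7   8      (+ = censored)
        # risk 7 at t=2 (d=2): S=5/7; risk 4 at t=5: S=(5/7)(3/4)=15/28;
        # risk 2 at t=7: S=(15/28)(1/2)=15/56; risk 1 at t=8: S=0
        curve = km_estimate([1, 2, 2, 3, 5, 6, 7, 8], [0, 1, 1, 0, 1, 0, 1, 1])
        assert np.allclose(curve.survival_prob, [5 / 7, 15 / 28, 15 / 56, 0.0])
        assert np.array_equal(curve.at_risk, [7, 4, 2, 1])
        assert curve.median == 7.0  # first time with S(t) <= 0.5

    def test_curve_is_monotone_nonincreasing_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            t = rng.exponential(50, 30)
            e = rng.random(30) < 0.5
            s = km_estimate(t, e).survival_prob
            assert np.all(np.diff(s) <= 1e-12)
            assert np.all((s >= 0) & (s <= 1))


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1, 2, 3, 4] * 2
        e = [1] * 8
        g = [0] * 4 + [1] * 4
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_group_example_matches_lifelines_and_oe_table(self):
        from lifelines.statistics import logrank_test as ll_logrank

        t = [3, 5, 7, 9, 11, 4, 6, 8, 10, 12]
        e = [1, 1, 0, 1, 1, 1, 0, 1, 1, 0]
        g = [0] * 5 + [1] * 5
        chi2, p, table = logrank_test(t, e, g, return_table=True)
        ref = ll_logrank(np.array(t[:5]), np.array(t[5:]), np.array(e[:5]), np.array(e[5:]))
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)
        # observed and expected totals agree across groups
        assert table["O_0"].sum() + table["O_1"].sum() == sum(e)
        assert table["E_0"].sum() + table["E_1"].sum() == pytest.approx(sum(e))

    def test_group_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(100, 30)
        e = rng.random(30) < 0.7
        g = rng.integers(0, 2, 30)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2"):
            logrank_test([1, 2, 3], [1, 1, 1], [0, 0, 0])

    def test_three_group_statistic_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(9)
        t = rng.exponential(100, 45)
        e = rng.random(45) < 0.8
        g = rng.integers(0, 3, 45)
        chi2, p = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


def grid_partial_likelihood_argmax(x, t, e):
    """Oracle: maximize the explicit tie-free Cox partial likelihood on a grid
    followed by scalar refinement."""
    x = np.asarray(x, float)
    t = np.asarray(t, float)
    e = np.asarray(e, bool)

    def nll(beta):
        ll = 0.0
        for i in np.nonzero(e)[0]:
            risk = t >= t[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return -ll

    grid = np.linspace(-5, 5, 2001)
    best = grid[int(np.argmin([nll(b) for b in grid]))]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(nll, bounds=(best - 0.02, best + 0.02), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


class TestCox:
    def test_tie_free_n6_matches_grid_maximized_partial_likelihood(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        t = np.array([5.0, 3.0, 9.0, 1.0, 7.0, 11.0])
        e = np.array([1, 1, 1, 1, 1, 0], dtype=bool)
        res = cox_fit(pd.DataFrame({"x": x}), t, e)
        oracle = grid_partial_likelihood_argmax(x, t, e)
        assert res.coef[0] == pytest.approx(oracle, abs=1e-4)

    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(5)
        n = 1500
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(100, n)
        res = cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, bool))
        assert abs(res.coef[0]) < 0.1

    def test_binary_covariate_recovers_rate_ratio(self):
        # exponential groups with rates 1/50 and 1/100: log rate ratio = log 2
        rng = np.random.default_rng(0)
        n = 2000
        x = np.repeat([0.0, 1.0], n // 2)
        t = np.where(x == 1, rng.exponential(50, n), rng.exponential(100, n))
        res = cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, bool))
        assert res.coef[0] == pytest.approx(np.log(2), abs=0.05)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1.0] * 6}), [1, 2, 3, 4, 5, 6], [1] * 6)

    def test_complete_separation_rejected(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        t = np.concatenate([np.arange(1, 11), np.arange(100, 110)])
        with pytest.raises(ValueError):
            cox_fit(pd.DataFrame({"x": x}), t, np.ones(20, bool))

    def test_hazard_ratio_and_ci_consistent(self):
        rng = np.random.default_rng(7)
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(100 / (1 + x), n)
        res = cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, bool))
        assert res.hazard_ratio[0] == pytest.approx(np.exp(res.coef[0]))
        assert res.ci_lower[0] < res.hazard_ratio[0] < res.ci_upper[0]


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        x = np.linspace(1, 10, 20)
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_equals_pearson_on_midranks(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 10, 30).astype(float)  # ties on purpose
        y = rng.integers(0, 10, 30).astype(float)
        rho, _ = spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], rel=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def exhaustive_youden(score, label):
    """Oracle: try every candidate cutoff, smallest wins ties."""
    s = np.asarray(score, float)
    y = np.asarray(label, bool)
    best_c, best_j = None, -np.inf
    for c in np.concatenate(([s.min() - 1], np.unique(s))):
        sens = (s[y] > c).mean()
        spec = (s[~y] <= c).mean()
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return best_c, best_j


class TestROC:
    def test_perfect_separation(self):
        r = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert 3 <= r.youden_cutoff < 10
        assert r.youden_index == 1.0

    def test_symmetric_uninformative_score_gives_half_auc(self):
        score = [1, 2, 3, 4, 1, 2, 3, 4]
        label = [0, 0, 0, 0, 1, 1, 1, 1]
        assert roc_youden(score, label).auc == pytest.approx(0.5)

    def test_cutoff_matches_exhaustive_search(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            s = rng.normal(size=40) + rng.integers(0, 2, 40)
            y = rng.integers(0, 2, 40)
            if y.min() == y.max():
                continue
            r = roc_youden(s, y)
            c, j = exhaustive_youden(s, y)
            assert r.youden_cutoff == pytest.approx(c)
            assert r.youden_index == pytest.approx(j)

    def test_auc_equals_mann_whitney_u_identity(self):
        rng = np.random.default_rng(13)
        s = rng.normal(size=60)  # continuous: tie-free almost surely
        y = rng.integers(0, 2, 60).astype(bool)
        r = roc_youden(s, y)
        u = sum((si > sj) for si in s[y] for sj in s[~y])
        assert r.auc == pytest.approx(u / (y.sum() * (~y).sum()))

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(14)
        s = rng.normal(size=80)
        y = rng.integers(0, 2, 80)
        assert roc_youden(s, y).auc == pytest.approx(roc_auc_score(y, s), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_youden([1, 2, 3], [1, 1, 1])


class TestSynergyAnalysis:
    def test_ordered_medians_under_additive_hazards(self):
        cohort, _ = lk.make_cohort(lk.CohortSpec(n_patients=300, seed=21))
        curves, comp = lk.synergy_analysis(cohort)
        assert curves["both"].median < curves["either"].median < curves["neither"].median
        assert set(comp["comparison"]) == {"both_vs_either", "neither_vs_either"}

    def test_single_group_cohort_warns_and_skips(self):
        df = pd.DataFrame({
            "pfs_days": [10.0, 20.0, 30.0],
            "pfs_event": [True, True, False],
            "synergy_group": ["neither"] * 3,
        })
        with pytest.warns(UserWarning):
            curves, comp = lk.synergy_analysis(df)
        assert comp.empty and set(curves) == {"neither"}
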