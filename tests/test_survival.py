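"""Survival statistics: hand-computed oracles and lifelines cross-checks.

lifelines is used here strictly as an independent reference
implementation; the package's own estimators are under test.
"""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from aortapet.survival import (
    cohen_kappa,
    concordance_percent,
    cox_fit,
    km_estimate,
    logrank_test,
    tertile_stratify,
)


class TestTertiles:
    def test_one_to_nine_splits_into_thirds(self):
        labels, (t1, t2) = tertile_stratify(list(range(1, 10)))
        assert list(labels) == ["low"] * 3 + ["medium"] * 3 + ["high"] * 3
        assert 3 <= t1 < 4 and 6 <= t2 < 7

    def test_boundary_ties_go_to_lower_group(self):
        values = [1, 2, 2, 2, 5, 9]
        labels, (t1, _) = tertile_stratify(values)
        assert t1 == pytest.approx(2.0)
        assert all(l == "low" for l, v in zip(labels, values) if v == 2)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            tertile_stratify([1.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            tertile_stratify([3.0] * 10)
        with pytest.raises(ValueError):
            tertile_stratify([1.0, np.nan, 2.0])


class TestKaplanMeier:
    def test_no_events_gives_flat_survival(self):
        curve = km_estimate([1.0, 2.0, 3.0], [False, False, False])
        assert curve.event_times.size == 0
        assert curve.survival_at(5.0) == 1.0

    def test_all_events_hand_product_limit(self):
        curve = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_censoring_convention_hand_example(self):
        # events at 1 and 3, censored at 2: S = 2/3 at t=1, 0 at t=3
        curve = km_estimate([1.0, 2.0, 3.0], [True, False, True])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 1])

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2.0, size=60)
        curve = km_estimate(t, np.ones(60, bool))
        for u, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx((t > u).mean())

    def test_matches_lifelines_with_ties_and_censoring(self):
        rng = np.random.default_rng(1)
        t = np.round(rng.exponential(2.0, size=80), 1) + 0.1
        e = rng.random(80) > 0.3
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_.loc[curve.event_times, "KM_estimate"].to_numpy()
        np.testing.assert_allclose(curve.survival, ref, atol=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [True, True])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([True, True, False, True] * 2)
        g = np.array(["low"] * 4 + ["high"] * 4, dtype=object)
        res = logrank_test(g, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_three_groups_df_two(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(2.0, 30)
        g = np.array(["low", "medium", "high"] * 10, dtype=object)
        res = logrank_test(g, t, np.ones(30, bool))
        assert res.df == 2
        assert set(res.pairwise) == {
            ("low", "medium"),
            ("low", "high"),
            ("medium", "high"),
        }

    def test_invariant_under_monotone_time_transform(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1.0, 40) + 0.1
        e = rng.random(40) > 0.2
        g = np.where(rng.random(40) > 0.5, "low", "high").astype(object)
        a = logrank_test(g, t, e)
        b = logrank_test(g, np.exp(t), e)  # strictly increasing transform
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)

    def test_matches_lifelines_three_groups(self):
        rng = np.random.default_rng(4)
        n = 90
        g = np.array(["low", "medium", "high"] * 30, dtype=object)
        rate = {"low": 0.2, "medium": 0.3, "high": 0.6}
        t = np.array([rng.exponential(1 / rate[x]) for x in g])
        c = rng.uniform(0, 8, n)
        e = t <= c
        T = np.minimum(t, c)
        res = logrank_test(g, T, e)
        ref = multivariate_logrank_test(T, g, e)
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            logrank_test(["low"] * 5, np.ones(5), np.ones(5, bool))


class TestCox:
    @staticmethod
    def sim(seed, n=200, beta=0.5, ties=False):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        age = rng.normal(60, 10, n)
        t = rng.exponential(1 / (0.1 * np.exp(beta * x)))
        if ties:
            t = np.ceil(t * 2) / 2
        c = rng.uniform(0, 15, n)
        return np.column_stack([x, age]), np.minimum(t, c), t <= c

    def test_matches_lifelines_with_ties(self):
        X, T, e = self.sim(0, ties=True)
        fit = cox_fit(X, T, e, names=["x", "age"])
        df = pd.DataFrame({"T": T, "E": e, "x": X[:, 0], "age": X[:, 1]})
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coefficients, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(
            fit.standard_errors, ref.standard_errors_.values, atol=1e-5
        )
        assert fit.lrt_statistic == pytest.approx(
            ref.log_likelihood_ratio_test().test_statistic, abs=1e-5
        )
        assert fit.converged and fit.lrt_statistic >= 0

    def test_null_covariate_is_near_zero(self):
        rng = np.random.default_rng(10)
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n)  # hazard independent of x
        fit = cox_fit(x, t, np.ones(n, bool))
        assert abs(fit.wald_z[0]) < 2.5
        assert abs(fit.coefficients[0]) < 0.15

    def test_efron_equals_breslow_without_ties(self):
        X, T, e = self.sim(1, ties=False)
        assert np.unique(T).size == T.size
        fe = cox_fit(X, T, e, ties="efron")
        fb = cox_fit(X, T, e, ties="breslow")
        np.testing.assert_allclose(fe.coefficients, fb.coefficients, atol=1e-10)

    def test_wald_z_is_coef_over_se(self):
        X, T, e = self.sim(2)
        fit = cox_fit(X, T, e)
        np.testing.assert_allclose(
            fit.wald_z, fit.coefficients / fit.standard_errors
        )

    def test_input_validation(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.ones(10), np.arange(1, 11.0), np.ones(10, bool))
        with pytest.raises(ValueError, match="event"):
            cox_fit(np.arange(10.0), np.arange(1, 11.0), np.zeros(10, bool))


class TestAgreement:
    def test_kappa_diagonal_table_is_one(self):
        res = cohen_kappa(np.diag([10, 20, 30]))
        assert res.kappa == pytest.approx(1.0)
        assert res.ci95[0] <= res.kappa <= res.ci95[1]

    def test_kappa_independent_margins_is_zero(self):
        row = np.array([20, 30, 50], float)
        col = np.array([40, 40, 20], float)
        table = np.outer(row, col)  # chance-level agreement by construction
        assert cohen_kappa(table).kappa == pytest.approx(0.0, abs=1e-12)

    def test_kappa_hand_computed_table(self):
        table = [[30, 10, 5], [10, 20, 15], [5, 15, 35]]
        n = 145
        po = 85 / n
        pe = (45 * 45 + 45 * 45 + 55 * 55) / n**2
        expected = (po - pe) / (1 - pe)
        res = cohen_kappa(table)
        assert res.kappa == pytest.approx(expected)
        se = np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
        assert res.ci95 == pytest.approx((expected - 1.96 * se, expected + 1.96 * se))

    def test_kappa_invariant_under_label_permutation(self):
        rng = np.random.default_rng(11)
        table = rng.integers(1, 40, size=(3, 3))
        base = cohen_kappa(table).kappa
        perm = [2, 0, 1]
        permuted = table[np.ix_(perm, perm)]
        assert cohen_kappa(permuted).kappa == pytest.approx(base)

    def test_kappa_errors(self):
        with pytest.raises(ValueError):
            cohen_kappa(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            cohen_kappa([[1, 2], [3, 4], [5, 6]])
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa([[5, 0, 0], [0, 0, 0], [0, 0, 0]])

    def test_concordance_trivial_cases(self):
        a = np.array(["low", "medium", "high", "low"], dtype=object)
        overall, per = concordance_percent(a, a)
        assert overall == 100.0 and set(per.values()) == {100.0}
        b = np.array(["medium", "high", "low", "high"], dtype=object)
        overall, per = concordance_percent(a, b)
        assert overall == 0.0

    def test_concordance_half_match(self):
        a = np.array(["low"] * 5 + ["high"] * 5, dtype=object)
        b = np.array(["low"] * 5 + ["low"] * 5, dtype=object)
        overall, per = concordance_percent(a, b)
        assert overall == 50.0
        assert per["low"] == 100.0 and per["high"] == 0.0

    def test_concordance_empty_errors(self):
        with pytest.raises(ValueError):
            concordance_percent([], [])
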