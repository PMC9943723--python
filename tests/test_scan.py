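"""Trait preprocessing, linear/logistic scans, multiplicity, conditioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvphewas.scan import (
    burden_comparison,
    conditional_scan,
    effective_tests,
    fit_logistic,
    inverse_normal_transform,
    linear_scan,
    logistic_scan,
    residualize_continuous,
    select_covariates_binary,
    significance_threshold,
    trait_correlation,
)
from conftest import toy_matrix


class TestInverseNormal:
    def test_blom_n3(self):
        out = inverse_normal_transform([10.0, 20.0, 30.0])
        expect = stats.norm.ppf([(1 - 0.375) / 3.25, 0.5, (3 - 0.375) / 3.25])
        np.testing.assert_allclose(out, expect)

    def test_median_scores_zero(self):
        out = inverse_normal_transform([5.0, 1.0, 9.0, 2.0, 7.0])
        assert out[np.argsort([5.0, 1.0, 9.0, 2.0, 7.0])[2]] == pytest.approx(0.0)

    def test_monotone_invariance(self):
        x = np.array([0.3, 2.0, 1.1, 5.2, 0.9])
        np.testing.assert_allclose(inverse_normal_transform(x),
                                   inverse_normal_transform(np.exp(x)))

    def test_missing_preserved(self):
        out = inverse_normal_transform([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="identical"):
            inverse_normal_transform([2.0, 2.0, 2.0])


class TestResidualize:
    def test_orthogonal_covariate_centers(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        c = pd.DataFrame({"c": [1.0, -1.0, -1.0, 1.0]})  # orthogonal to linear trend
        np.testing.assert_allclose(residualize_continuous(y, c), y - y.mean())

    def test_exact_linear_gives_zero(self):
        x = np.arange(10.0)
        y = 2 + 3 * x
        out = residualize_continuous(y, pd.DataFrame({"x": x}))
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_hand_ols_five_points(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        b = np.cov(x, y, bias=True)[0, 1] / x.var()
        a = y.mean() - b * x.mean()
        np.testing.assert_allclose(residualize_continuous(y, pd.DataFrame({"x": x})),
                                   y - (a + b * x))

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError, match="covariates"):
            residualize_continuous(np.array([1.0, 2.0]),
                                   pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}))


class TestLinearScan:
    def test_exact_fit(self):
        states = np.array([[0.0, 0, 0, 1, 1, 1]])
        m = toy_matrix(states)
        y = pd.Series([0.0, 0, 0, 1, 1, 1], name="y")
        res = linear_scan(m, "duplication-only", y)
        assert res.loc[0, "effect"] == pytest.approx(1.0)
        assert res.loc[0, "p"] < 1e-10

    def test_group_mean_difference(self):
        states = np.array([[0.0] * 4 + [1.0] * 4])
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0], name="y")
        res = linear_scan(toy_matrix(states), "U-shape", y)
        assert res.loc[0, "effect"] == pytest.approx(6.5 - 2.5)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        states = (rng.uniform(size=(1, 300)) < 0.1).astype(float)
        y = rng.standard_normal(300) + 0.5 * states[0]
        res = linear_scan(toy_matrix(states), "mirror", pd.Series(y, name="y"))
        fit = sm.OLS(y, sm.add_constant(states[0])).fit()
        assert res.loc[0, "effect"] == pytest.approx(fit.params[1])
        assert res.loc[0, "se"] == pytest.approx(fit.bse[1])
        assert res.loc[0, "p"] == pytest.approx(fit.pvalues[1])

    def test_degenerate_probe_skipped(self):
        states = np.array([[0.0] * 6, [0.0, 0, 0, 1, 1, 1]])
        res = linear_scan(toy_matrix(states), "mirror",
                          pd.Series(np.arange(6.0), name="y"))
        assert res.loc[0, "skip_reason"] == "degenerate dosage"
        assert res.loc[1, "skip_reason"] is None

    def test_class_counts_reported(self):
        states = np.array([[-1.0, 0, 0, 1, 1, 0]])
        res = linear_scan(toy_matrix(states), "mirror",
                          pd.Series([1.0, 2, 3, 4, 5, 6], name="y"))
        assert (res.loc[0, ["n_del", "n_neutral", "n_dup"]] == [1, 3, 2]).all()

    def test_missing_trait_values_masked(self):
        states = np.array([[0.0, 0, 1, 1, 0, 1]])
        y = pd.Series([1.0, np.nan, 2.0, 2.0, 1.0, 2.0], name="y")
        res = linear_scan(toy_matrix(states), "duplication-only", y)
        assert res.loc[0, "effect"] == pytest.approx(1.0)


class TestLogisticScan:
    def test_or_one_for_identical_split(self):
        states = np.hstack([np.ones(20), np.zeros(20)])[None, :]
        y = pd.Series(np.tile([1.0] * 10 + [0.0] * 10, 2), name="d")
        res = logistic_scan(toy_matrix(states), "duplication-only", y)
        assert res.loc[0, "effect"] == pytest.approx(1.0, abs=1e-6)

    def test_2x2_closed_form(self):
        states = np.hstack([np.ones(100), np.zeros(100)])[None, :]
        y = pd.Series(np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)], name="d")
        res = logistic_scan(toy_matrix(states), "duplication-only", y)
        assert np.log(res.loc[0, "effect"]) == pytest.approx(np.log(20 * 90 / (80 * 10)))

    def test_zero_affected_carriers_firth(self):
        states = np.hstack([np.ones(30), np.zeros(370)])[None, :]
        y = pd.Series(np.r_[np.zeros(30), np.ones(40), np.zeros(330)], name="d")
        res = logistic_scan(toy_matrix(states), "duplication-only", y)
        assert bool(res.loc[0, "fallback_flag"])
        assert np.isfinite(res.loc[0, "l95"]) and np.isfinite(res.loc[0, "u95"])
        assert res.loc[0, "u95"] > res.loc[0, "effect"] > res.loc[0, "l95"]

    def test_constant_outcome_skipped(self):
        states = np.array([[0.0, 1, 0, 1]])
        y = pd.Series([1.0, 1, 1, 1], name="d")
        res = logistic_scan(toy_matrix(states), "mirror", y)
        assert res.loc[0, "skip_reason"] is not None

    def test_with_covariates_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        n = 500
        states = (rng.uniform(size=(1, n)) < 0.1).astype(float)
        c = rng.standard_normal(n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(-1 + states[0] + 0.5 * c)))).astype(float)
        res = logistic_scan(toy_matrix(states), "duplication-only",
                            pd.Series(y, name="d"), pd.DataFrame({"c": c}))
        fit = sm.Logit(y, sm.add_constant(np.column_stack([states[0], c]))).fit(disp=0)
        assert np.log(res.loc[0, "effect"]) == pytest.approx(fit.params[1], rel=1e-5)
        assert res.loc[0, "se"] == pytest.approx(fit.bse[1], rel=1e-4)


class TestCovariateSelection:
    def test_predictive_covariate_selected(self):
        rng = np.random.default_rng(2)
        n = 800
        c = rng.standard_normal(n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-c))).astype(float)
        sel, _ = select_covariates_binary(pd.Series(y), pd.DataFrame({"c": c}))
        assert sel == ["c"]

    def test_null_covariate_rate(self):
        """Independent covariates are selected at roughly the nominal 5% rate."""
        rng = np.random.default_rng(3)
        n, reps = 400, 200
        y = (rng.uniform(size=n) < 0.3).astype(float)
        cands = pd.DataFrame(rng.standard_normal((n, reps)),
                             columns=[f"c{i}" for i in range(reps)])
        sel, _ = select_covariates_binary(pd.Series(y), cands)
        rate = len(sel) / reps
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_empty_candidates(self):
        y = pd.Series([0.0, 1.0, 0.0, 1.0])
        sel, _ = select_covariates_binary(y, pd.DataFrame(index=range(4)))
        assert sel == []

    def test_one_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            select_covariates_binary(pd.Series([1.0, 1.0]), pd.DataFrame({"c": [1.0, 2.0]}))


class TestEffectiveTests:
    def test_identical_probes_one(self):
        assert effective_tests(np.ones((7, 7))) == 1

    def test_uncorrelated_full_count(self):
        for k in (5, 50, 199):
            assert effective_tests(np.eye(k)) == k
        # boundary: at k=200 the top 199 unit eigenvalues reach exactly
        # 0.995 * trace, so 199 tests suffice
        assert effective_tests(np.eye(200)) == 199

    def test_equicorrelation_closed_form(self):
        # eigenvalues of the 3x3 r=0.9 matrix: (1+2r, 1-r, 1-r) = (2.8, .1, .1)
        corr = np.full((3, 3), 0.9)
        np.fill_diagonal(corr, 1.0)
        ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(ev, [2.8, 0.1, 0.1])
        m = int(np.searchsorted(np.cumsum(ev), 0.995 * ev.sum() - 1e-12) + 1)
        assert effective_tests(corr) == m == 3

    def test_monotone_under_duplication(self):
        """Appending a perfectly correlated probe never raises the count."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((6, 100))
        base = np.corrcoef(X)
        dup = np.corrcoef(np.vstack([X, X[0]]))
        assert effective_tests(dup) <= effective_tests(base) + 0

    def test_asymmetric_rejected(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            effective_tests(bad)


class TestSignificanceThreshold:
    def test_published_counts(self):
        res = significance_threshold(6, 16, 113)
        assert res.neff_total == 774
        assert res.alpha == pytest.approx(6.5e-5, rel=0.01)

    def test_single_test(self):
        res = significance_threshold(1, 1, 0)
        assert res.neff_total == 1 and res.alpha == 0.05

    def test_small_arithmetic(self):
        res = significance_threshold(2, 3, 4)
        assert res.neff_total == 14
        assert res.alpha == pytest.approx(0.05 / 14)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            significance_threshold(0, 1, 1)


class TestConditionalScan:
    def test_collinear_probes_one_lead(self):
        rng = np.random.default_rng(5)
        carrier = (rng.uniform(size=2000) < 0.05).astype(float)
        states = np.vstack([carrier, carrier])
        y = pd.Series(0.8 * carrier + rng.standard_normal(2000), name="y")
        leads = conditional_scan(toy_matrix(states), "mirror", y, alpha=1e-3)
        assert len(leads) == 1

    def test_two_independent_signals(self):
        rng = np.random.default_rng(6)
        c1 = (rng.uniform(size=4000) < 0.05).astype(float)
        c2 = (rng.uniform(size=4000) < 0.05).astype(float)
        states = np.vstack([c1, c1, c2, c2])
        y = pd.Series(0.7 * c1 + 0.7 * c2 + rng.standard_normal(4000), name="y")
        leads = conditional_scan(toy_matrix(states), "mirror", y, alpha=1e-3)
        assert len(leads) == 2
        assert {leads.loc[0, "probe_id"][:2], leads.loc[1, "probe_id"][:2]} == {"p0", "p2"} or \
            len({leads.loc[0, "probe_id"], leads.loc[1, "probe_id"]}) == 2

    def test_no_signal_empty(self):
        rng = np.random.default_rng(7)
        states = (rng.uniform(size=(3, 500)) < 0.05).astype(float)
        y = pd.Series(rng.standard_normal(500), name="y")
        leads = conditional_scan(toy_matrix(states), "mirror", y, alpha=1e-5)
        assert len(leads) == 0

    def test_terminates_within_probe_count(self):
        rng = np.random.default_rng(8)
        states = (rng.uniform(size=(5, 3000)) < 0.05).astype(float)
        y = pd.Series(states.sum(axis=0) + 0.1 * rng.standard_normal(3000), name="y")
        leads = conditional_scan(toy_matrix(states), "U-shape", y, alpha=0.01)
        assert len(leads) <= 5


class TestBurden:
    def test_enumerated_3v3(self):
        """All carrier counts above all neutral ones: exact two-sided p = 0.1."""
        counts = np.array([4.0, 5, 6, 1, 2, 3])
        status = np.array([1.0, 1, 1, 0, 0, 0])
        p_del, p_dup = burden_comparison(counts, status)
        assert np.isnan(p_del)
        assert p_dup == pytest.approx(0.1)

    def test_identical_distributions(self):
        counts = np.array([1.0, 2, 3, 1, 2, 3])
        status = np.array([-1.0, -1, -1, 0, 0, 0])
        p_del, p_dup = burden_comparison(counts, status)
        assert p_del == pytest.approx(1.0)
        assert np.isnan(p_dup)

    def test_all_equal_counts(self):
        counts = np.ones(8)
        status = np.array([1.0, 1, 0, 0, 0, 0, -1, -1])
        p_del, p_dup = burden_comparison(counts, status)
        assert p_del == pytest.approx(1.0) and p_dup == pytest.approx(1.0)


def test_type_one_error_calibrated(carrier_matrix):
    """Null linear scan: rejection rates match alpha at 0.05 and 0.01."""
    rng = np.random.default_rng(11)
    n_traits = 500
    Y = pd.DataFrame(rng.standard_normal((carrier_matrix.n_samples, n_traits)),
                     columns=[f"t{i}" for i in range(n_traits)])
    res = linear_scan(carrier_matrix, "mirror", Y)
    res = res[res["skip_reason"].isna()]
    n = len(res)
    for alpha in (0.05, 0.01):
        frac = (res["p"] < alpha).mean()
        # correlated probes reduce the effective test count; bound on SE uses
        # the number of independent probe blocks (2) times traits
        n_indep = 2 * n_traits
        assert abs(frac - alpha) <= 3 * np.sqrt(alpha * (1 - alpha) / n_indep)


def test_ushape_equals_dup_scan_on_dup_only_data():
    rng = np.random.default_rng(12)
    states = (rng.uniform(size=(4, 2000)) < 0.03).astype(float)
    y = pd.Series(rng.standard_normal(2000) + 0.4 * states[0], name="y")
    m = toy_matrix(states)
    a = linear_scan(m, "U-shape", y)
    b = linear_scan(m, "duplication-only", y)
    np.testing.assert_array_equal(a["effect"].to_numpy(), b["effect"].to_numpy())
    np.testing.assert_array_equal(a["p"].to_numpy(), b["p"].to_numpy())


def test_logistic_agrees_with_fisher_logor():
    """Dense 2x2 tables: logistic and Fisher log-OR within 10%."""
    states = np.hstack([np.ones(60), np.zeros(140)])[None, :]
    y = pd.Series(np.r_[np.ones(25), np.zeros(35), np.ones(40), np.zeros(100)], name="d")
    res = logistic_scan(toy_matrix(states), "duplication-only", y)
    table_logor = np.log((25 * 100) / (35 * 40))
    assert np.log(res.loc[0, "effect"]) == pytest.approx(table_logor, rel=0.1)


def test_trait_correlation_handles_missing():
    df = pd.DataFrame({"a": [1.0, 2, 3, np.nan], "b": [1.0, 2, 3, 4]})
    r = trait_correlation(df)
    assert r[0, 1] == pytest.approx(1.0)
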