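"""Exact confirmatory tests against brute-force oracles, retention logic."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvphewas.sensitivity import (
    apply_retention_rules,
    carrier_table,
    cochran_armitage_trend,
    fisher_exact_2x2,
    mirror_table,
    residual_confirmation,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_rank_sum(x, y, alternative):
    """Tail probability over every assignment of pooled values to group x."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    le = ge = total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        le += w <= obs + 1e-9
        ge += w >= obs - 1e-9
    if alternative == "less":
        return le / total
    if alternative == "greater":
        return ge / total
    return min(1.0, 2 * min(le / total, ge / total))


def brute_force_fisher(table):
    """Probability-mass two-sided Fisher p from the hypergeometric pmf."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def pmf(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(max(0, c1 - r2), min(r1, c1) + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))


class TestWilcoxon:
    def test_one_sided_small(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4], "less") == pytest.approx(1 / 6)

    def test_two_sided_separated(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_small_n(self, seed):
        """Random small samples (ties included) agree with full enumeration."""
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 7), rng.integers(1, 7)
        vals = rng.integers(0, 5, size=n1 + n2).astype(float)  # ties likely
        x, y = vals[:n1], vals[n1:]
        for alt in ("less", "greater", "two-sided"):
            assert wilcoxon_rank_sum(x, y, alt) == pytest.approx(
                brute_force_rank_sum(x, y, alt))

    def test_two_sided_at_least_one_sided(self):
        rng = np.random.default_rng(9)
        x, y = rng.standard_normal(5), rng.standard_normal(6)
        two = wilcoxon_rank_sum(x, y)
        assert two >= min(wilcoxon_rank_sum(x, y, "less"),
                          wilcoxon_rank_sum(x, y, "greater")) - 1e-12

    def test_large_sample_asymptotic_close_to_exact_ranksums(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(300)
        y = rng.standard_normal(400) + 0.2
        ours = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert ours == pytest.approx(ref)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [([[2, 0], [0, 2]], 1 / 3), ([[5, 5], [5, 5]], 1.0),
         ([[3, 1], [1, 3]], 0.4857142857142857)],
    )
    def test_known_tables(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-9)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_brute_force_all_small_tables(self):
        """Every 2x2 table with total <= 12 agrees with direct enumeration."""
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                            assert fisher_exact_2x2(t) == 1.0
                        else:
                            assert fisher_exact_2x2(t) == pytest.approx(
                                brute_force_fisher(t), rel=1e-9)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])


class TestCochranArmitage:
    def test_flat_case_fractions(self):
        assert cochran_armitage_trend([[5, 5, 5], [5, 5, 5]]) == pytest.approx(1.0)

    def test_matches_permutation_oracle(self):
        """Trend statistic p vs permutation distribution of the score sum."""
        table = np.array([[0, 10, 10], [10, 10, 0]])
        p_analytic = cochran_armitage_trend(table)
        # permutation oracle: shuffle case labels over individuals
        scores = np.repeat([-1.0, 0.0, 1.0], table.sum(axis=0))
        labels = np.zeros(int(table.sum()))
        pos = 0
        for j in range(3):
            labels[pos: pos + table[0, j]] = 1
            pos += int(table[:, j].sum())
        # observed score sum among cases
        def case_sum(lbl):
            return float(scores[lbl == 1].sum())
        obs = abs(case_sum(labels) - labels.sum() * scores.mean())
        rng = np.random.default_rng(0)
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if abs(case_sum(perm) - labels.sum() * scores.mean()) >= obs - 1e-9:
                hits += 1
        p_perm = hits / n_perm
        assert p_analytic == pytest.approx(p_perm, abs=0.01)

    def test_reversed_order_same_p(self):
        t = np.array([[2, 5, 9], [8, 5, 1]])
        assert cochran_armitage_trend(t) == pytest.approx(
            cochran_armitage_trend(t[:, ::-1]))

    def test_single_class_undefined(self):
        assert np.isnan(cochran_armitage_trend([[3, 0, 0], [4, 0, 0]]))


class TestResidualConfirmation:
    def test_reduces_to_covariate_free_regression(self):
        """No covariates: p equals INT-outcome-on-dosage linear regression."""
        from cnvphewas.scan import _ols_many, inverse_normal_transform

        rng = np.random.default_rng(13)
        n = 400
        d = (rng.uniform(size=n) < 0.2).astype(float)
        y = (rng.uniform(size=n) < 0.3 + 0.2 * d).astype(float)
        p = residual_confirmation(y, None, d)
        z = inverse_normal_transform(y)
        _, _, p_ref, _ = _ols_many(d, z[:, None])
        assert p == pytest.approx(float(p_ref[0]), rel=1e-9)

    def test_null_calibration(self):
        """Dosage independent of outcome: p below 0.05 in about 5% of reps."""
        rng = np.random.default_rng(14)
        n, reps = 500, 200
        hits = 0
        for _ in range(reps):
            d = (rng.uniform(size=n) < 0.1).astype(float)
            c = rng.standard_normal(n)
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-0.5 * c))).astype(float)
            if residual_confirmation(y, c, d) < 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_power_on_strong_effect(self):
        """OR 5 at 1% carriers, n=20,000: confirmation p < 0.005 in >=90% of seeds."""
        hits = 0
        seeds = 20
        for seed in range(seeds):
            rng = np.random.default_rng(100 + seed)
            n = 20_000
            d = (rng.uniform(size=n) < 0.01).astype(float)
            eta = np.log(0.1 / 0.9) + np.log(5) * d
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
            if residual_confirmation(y, None, d) < 0.005:
                hits += 1
        assert hits >= 0.9 * seeds

    def test_degenerate_dosage_missing(self):
        y = np.array([0.0, 1, 0, 1])
        assert np.isnan(residual_confirmation(y, None, np.zeros(4)))


class TestRetention:
    def _scan(self, model, kind):
        return pd.DataFrame([{"probe_id": "p1", "trait": "t", "model": model,
                              "trait_kind": kind}])

    def _sens(self, **kw):
        base = {"probe_id": "p1", "trait": "t", "model": kw.pop("model"),
                "wilcoxon_p": np.nan, "fisher_p": np.nan, "trend_p": np.nan,
                "residual_p": np.nan}
        base.update(kw)
        return pd.DataFrame([base])

    def test_mirror_trend_confirms(self):
        v = apply_retention_rules(self._scan("mirror", "binary"),
                                  self._sens(model="mirror", trend_p=1e-6, residual_p=0.1))
        assert bool(v.loc[0, "confirmed"])

    def test_both_routes_fail(self):
        v = apply_retention_rules(self._scan("duplication-only", "binary"),
                                  self._sens(model="duplication-only",
                                             fisher_p=0.01, residual_p=0.01))
        assert not v.loc[0, "confirmed"]

    def test_residual_route_confirms(self):
        v = apply_retention_rules(self._scan("duplication-only", "binary"),
                                  self._sens(model="duplication-only",
                                             fisher_p=0.01, residual_p=0.004))
        assert bool(v.loc[0, "confirmed"])

    def test_continuous_never_dropped(self):
        v = apply_retention_rules(self._scan("mirror", "continuous"),
                                  self._sens(model="mirror", wilcoxon_p=0.9))
        assert bool(v.loc[0, "confirmed"])
        assert not v.loc[0, "wilcoxon_agrees"]

    def test_missing_marks_incomplete(self):
        v = apply_retention_rules(self._scan("mirror", "binary"),
                                  self._sens(model="mirror", trend_p=np.nan,
                                             residual_p=0.1))
        assert bool(v.loc[0, "incomplete"])

    def test_monotone_in_confirmatory_p(self):
        """Lowering any confirmatory p never flips confirmed -> not confirmed."""
        rng = np.random.default_rng(15)
        for _ in range(50):
            f, r = rng.uniform(size=2)
            v1 = apply_retention_rules(
                self._scan("U-shape", "binary"),
                self._sens(model="U-shape", fisher_p=f, residual_p=r))
            v2 = apply_retention_rules(
                self._scan("U-shape", "binary"),
                self._sens(model="U-shape", fisher_p=f / 2, residual_p=r / 2))
            assert not (bool(v1.loc[0, "confirmed"]) and not bool(v2.loc[0, "confirmed"]))


def test_table_builders_exclude_missing():
    d = np.array([1.0, 1, 0, 0, np.nan])
    y = np.array([1.0, 0, 1, 0, 1])
    t = carrier_table(d, y)
    assert t.sum() == 4 and t[0, 0] == 1
    s = np.array([-1.0, 0, 1, np.nan, 0])
    m = mirror_table(s, np.array([1.0, 0, 1, 1, np.nan]))
    assert m.sum() == 3
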