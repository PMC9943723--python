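"""Confirmatory sensitivity tests for significant CNV associations.

Rare copy-number carriers make asymptotic regression p values fragile, so
each significant association is re-tested with a distribution-free or exact
procedure: Wilcoxon rank-sum for continuous traits; for binary traits,
Fisher's exact test (carrier-contrast models) or the Cochran-Armitage trend
test (mirror model), and a second route regressing inverse-normal
transformed residuals of the covariate-only logistic model on the dosage.
A significant binary association is retained when at least one of the two
routes confirms it.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .dosage import canonical_model
from .scan import _logistic_irls, inverse_normal_transform, _ols_many

#: Confirmation thresholds for binary associations.
FISHER_P = 0.005
TREND_P = 0.0005
RESIDUAL_P = 0.005

_EXACT_MAX_COMBOS = 200_000


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _exact_rank_sum_p(x, y, alternative):
    """Exact rank-sum tail probability by enumeration of all group splits.

    Handles ties through midranks.  Feasible when C(n1+n2, n1) is modest;
    used for the small samples where exactness matters.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    total = comb(len(pooled), n1)
    eps = 1e-9
    n_le = n_ge = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
    p_less, p_greater = n_le / total, n_ge / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p value for two samples.

    ``alternative`` refers to ``x``: "less" tests whether x tends to take
    smaller values than y.  Exact enumeration of rank splits when the number
    of splits is small (ties handled via midranks); exact Mann-Whitney
    recursion for tie-free larger samples with n1*n2 <= 1e6; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if comb(x.size + y.size, x.size) <= _EXACT_MAX_COMBOS:
        return float(_exact_rank_sum_p(x, y, alternative))
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (not has_ties and x.size * y.size <= 40_000) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Exact categorical tests


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Two-sidedness by the probability-mass rule (sum of hypergeometric
    probabilities no larger than the observed table's).  A zero row or
    column margin makes the table uninformative: p = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if not np.allclose(t, np.round(t)) or np.any(t < 0) or t.shape != (2, 2):
            raise ValueError("table must be 2x2 non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def cochran_armitage_trend(table3, scores=(-1.0, 0.0, 1.0)) -> float:
    """Cochran-Armitage trend test for a 2x3 case/control table.

    Rows are (cases, controls), columns the ordered copy-number classes
    (−1, 0, +1) scored linearly.  Returns the 1-df chi-square p value; NaN
    when fewer than two classes are populated.
    """
    t = np.asarray(table3, dtype=float)
    if t.shape != (2, 3) or np.any(t < 0):
        raise ValueError("table must be 2x3 with non-negative counts")
    s = np.asarray(scores, dtype=float)
    cases = t[0]
    n_i = t.sum(axis=0)
    if np.sum(n_i > 0) < 2:
        return float("nan")
    N = n_i.sum()
    R = cases.sum()
    if R == 0 or R == N:
        return float("nan")
    pbar = R / N
    u = np.sum(s * (cases - n_i * pbar))
    var = pbar * (1 - pbar) * (np.sum(s**2 * n_i) - np.sum(s * n_i) ** 2 / N)
    if var <= 0:
        return 1.0
    chi2 = u**2 / var
    return float(stats.chi2.sf(chi2, df=1))


def carrier_table(dosage, outcome) -> np.ndarray:
    """2x2 (carrier x case/control) table for a carrier-contrast dosage.

    Carriers are samples with dosage 1, non-carriers dosage 0; samples with
    missing dosage or outcome are excluded.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(outcome, dtype=float)
    ok = ~np.isnan(d) & ~np.isnan(y)
    d, y = d[ok], y[ok]
    return np.array(
        [
            [int(np.sum((d == 1) & (y == 1))), int(np.sum((d == 1) & (y == 0)))],
            [int(np.sum((d == 0) & (y == 1))), int(np.sum((d == 0) & (y == 0)))],
        ]
    )


def mirror_table(states, outcome) -> np.ndarray:
    """2x3 case/control table over copy-number classes (−1, 0, +1)."""
    s = np.asarray(states, dtype=float)
    y = np.asarray(outcome, dtype=float)
    ok = ~np.isnan(s) & ~np.isnan(y)
    s, y = s[ok], y[ok]
    return np.array(
        [
            [int(np.sum((s == c) & (y == 1))) for c in (-1, 0, 1)],
            [int(np.sum((s == c) & (y == 0))) for c in (-1, 0, 1)],
        ]
    )


# ---------------------------------------------------------------------------
# Residual-regression confirmation


def residual_confirmation(outcome, covariates, dosage) -> float:
    """Second confirmation route for binary associations.

    The binary outcome is fit on the selected covariates only (logistic);
    the deviance residuals of that fit are inverse-normal transformed and
    linearly regressed on the dosage.  Returns the slope's p value, NaN for
    degenerate dosage.
    """
    y = np.asarray(outcome, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if covariates is None or (hasattr(covariates, "shape") and np.ndim(covariates) == 2 and covariates.shape[1] == 0):
        C = np.empty((len(y), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    ok = ~np.isnan(y) & ~np.isnan(C).any(axis=1)
    X = np.column_stack([np.ones(int(ok.sum())), C[ok]])
    beta, _, conv = _logistic_irls(X, y[ok])
    mu = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))
    yv = y[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = -2 * (yv * np.log(mu) + (1 - yv) * np.log1p(-mu))
    resid = np.sign(yv - mu) * np.sqrt(np.maximum(dev, 0.0))
    z = inverse_normal_transform(resid)
    dv = d[ok]
    if np.all(np.isnan(dv)) or len(np.unique(dv[~np.isnan(dv)])) < 2:
        return float("nan")
    b, se, p, n = _ols_many(dv, z[:, None])
    return float(p[0])


# ---------------------------------------------------------------------------
# Retention logic


def apply_retention_rules(scan_results: pd.DataFrame, sensitivity_results: pd.DataFrame) -> pd.DataFrame:
    """Combine scan hits with sensitivity p values into retention verdicts.

    Binary associations are confirmed iff (Fisher p <= 0.005 for the
    carrier-contrast models, or Cochran-Armitage p <= 0.0005 for mirror) OR
    residual-regression p <= 0.005.  Continuous associations are annotated
    with Wilcoxon agreement but never dropped automatically.  Missing
    sensitivity values mark the verdict incomplete.
    """
    keys = ["probe_id", "trait", "model"]
    merged = scan_results.merge(sensitivity_results, on=keys, how="left", suffixes=("", "_sens"))
    verdicts = []
    for rec in merged.to_dict("records"):
        model = canonical_model(rec["model"])
        kind = rec.get("trait_kind")
        if not isinstance(kind, str):
            has_binary_tests = any(
                pd.notna(rec.get(c, np.nan)) for c in ("fisher_p", "trend_p", "residual_p")
            )
            kind = "binary" if has_binary_tests else "continuous"
        row = {k: rec[k] for k in keys}
        row["trait_kind"] = kind
        for c in ("wilcoxon_p", "fisher_p", "trend_p", "residual_p"):
            row[c] = rec.get(c, np.nan)
        if kind == "continuous":
            row["confirmed"] = True
            row["wilcoxon_agrees"] = bool(pd.notna(row["wilcoxon_p"]) and row["wilcoxon_p"] <= 0.05)
            row["incomplete"] = bool(pd.isna(row["wilcoxon_p"]))
        else:
            exact_p = row["trend_p"] if model == "mirror" else row["fisher_p"]
            exact_thr = TREND_P if model == "mirror" else FISHER_P
            route1 = pd.notna(exact_p) and exact_p <= exact_thr
            route2 = pd.notna(row["residual_p"]) and row["residual_p"] <= RESIDUAL_P
            row["confirmed"] = bool(route1 or route2)
            row["incomplete"] = bool(pd.isna(exact_p) or pd.isna(row["residual_p"]))
        verdicts.append(row)
    return pd.DataFrame(verdicts)
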