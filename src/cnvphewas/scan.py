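"""Probe-level association scanning and multiplicity control.

Continuous traits are rank-based inverse-normal transformed (INT), corrected
for covariates by OLS residualisation, and regressed on the encoded
copy-number dosage of each probe (simple linear regression, Wald test).
Binary traits are tested with logistic regression on the dosage plus
trait-specific covariates selected by univariable screening; fits that fail
to converge, or where a carrier-by-outcome cell is empty, fall back to
Firth-penalised logistic regression and are flagged.

Multiplicity is controlled through the effective number of independent
tests: the number of top eigenvalues of a correlation matrix needed to
capture a fixed fraction (default 99.5%) of its trace, computed separately
for probes, continuous traits and binary traits and combined as
``N_eff = N_eff_probes * (N_eff_continuous + N_eff_binary)`` with the
significance threshold ``alpha = 0.05 / N_eff``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .cnv_matrix import CnvMatrix
from .dosage import canonical_model, encode

RESULT_COLUMNS = [
    "probe_id", "bp", "trait", "model", "effect", "se", "l95", "u95", "p",
    "n_del", "n_neutral", "n_dup", "fallback_flag", "skip_reason",
]


# ---------------------------------------------------------------------------
# Trait preprocessing


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offset.

    Maps value of rank r (average ranks for ties) among n non-missing
    observations to ``Phi^{-1}((r - 3/8) / (n + 1/4))``; missing values stay
    missing.  Invariant under any strictly monotone transform of the input.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("inverse normal transform needs at least 2 non-missing values")
    if np.all(v[ok] == v[ok][0]):
        raise ValueError("all values identical; ranking impossible")
    ranks = stats.rankdata(v[ok])
    out[ok] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def residualize_continuous(trait, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of a (transformed) trait on covariates plus intercept.

    Collinear covariate columns are harmless (least-squares via lstsq);
    missing rows propagate to missing residuals.
    """
    y = np.asarray(trait, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(len(y)), C])
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    if ok.sum() <= X.shape[1]:
        raise ValueError("fewer observations than covariates")
    coef, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    out = np.full(len(y), np.nan)
    out[ok] = y[ok] - X[ok] @ coef
    return out


# ---------------------------------------------------------------------------
# Logistic fitting machinery (IRLS with Firth-penalised fallback)


def _logistic_irls(X, y, w=None, max_iter=60, tol=1e-9):
    """Newton-Raphson logistic fit; supports frequency weights.

    Returns (beta, cov, converged).  Singular information or diverging
    coefficients report converged=False.
    """
    n, k = X.shape
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = special.expit(eta)
        wt = w * mu * (1 - mu)
        info = X.T @ (X * wt[:, None])
        score = X.T @ (w * (y - mu))
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            if np.max(np.abs(beta)) > 30:  # separation: MLE off to infinity
                return beta, None, False
            try:
                cov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                return beta, None, False
            return beta, cov, True
    return beta, None, False


def _firth_logistic(X, y, w=None, max_iter=120, tol=1e-8):
    """Firth-penalised logistic regression (Jeffreys-prior bias reduction).

    Yields finite estimates under separation / empty cells; returns
    (beta, cov, converged).
    """
    n, k = X.shape
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = special.expit(eta)
        wt = w * mu * (1 - mu)
        info = X.T @ (X * wt[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return beta, None, False
        # leverage of each (weighted) observation in the working regression
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * wt
        score = X.T @ (w * (y - mu) + h * (0.5 - mu))
        step = info_inv @ score
        # step-halving for stability
        for _ in range(5):
            if np.max(np.abs(step)) < 5:
                break
            step = step / 2
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, info_inv, True
    return beta, info_inv, False


def fit_logistic(dosage, y, covariates=None, firth_fallback=True):
    """Fit outcome ~ dosage (+ covariates) by logistic regression.

    Returns dict with ``beta`` (log-odds per dosage unit), ``se``, ``p``,
    ``fallback`` (True when the Firth penalty was used) or None when the
    outcome is degenerate.  The fit collapses samples with identical design
    rows to frequency-weighted unique rows when no covariates are given,
    which makes large-n scans cheap.
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[-1] == 0):
        C = None
        ok = ~np.isnan(x) & ~np.isnan(y)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        ok = ~np.isnan(x) & ~np.isnan(y) & ~np.isnan(C).any(axis=1)
        C = C[ok]
    x, y = x[ok], y[ok]
    if len(np.unique(y)) < 2 or len(np.unique(x)) < 2:
        return None

    if C is None:
        # grouped sufficient statistics: at most 3 dosage levels x 2 outcomes
        levels, inv = np.unique(x, return_inverse=True)
        cell = inv * 2 + y.astype(int)
        counts = np.bincount(cell, minlength=2 * len(levels)).astype(float)
        keep = counts > 0
        Xg = np.column_stack([np.ones(2 * len(levels)), np.repeat(levels, 2)])[keep]
        yg = np.tile([0.0, 1.0], len(levels))[keep]
        wg = counts[keep]
        # any carrier level with an empty outcome cell => separation-prone
        carrier = np.repeat(levels, 2) != 0
        empty_cell = bool(np.any(~keep & carrier))
        beta, cov, conv = _logistic_irls(Xg, yg, wg)
        fallback = False
        if (not conv or empty_cell) and firth_fallback:
            beta, cov, conv = _firth_logistic(Xg, yg, wg)
            fallback = True
    else:
        X = np.column_stack([np.ones(len(x)), x, C])
        beta, cov, conv = _logistic_irls(X, y)
        fallback = False
        if not conv and firth_fallback:
            beta, cov, conv = _firth_logistic(X, y)
            fallback = True
    if not conv or cov is None:
        return None
    se = float(np.sqrt(cov[1, 1]))
    b = float(beta[1])
    z = b / se if se > 0 else np.inf * np.sign(b)
    p = float(max(2 * stats.norm.sf(abs(z)), 5e-324))
    return {"beta": b, "se": se, "p": p, "fallback": fallback}


def select_covariates_binary(trait, candidates: pd.DataFrame, alpha: float = 0.05):
    """Univariable logistic screening of candidate covariates.

    Each candidate is tested alone against the binary trait; candidates with
    Wald p <= alpha are selected.  Candidates whose univariable fit shows
    separation are selected and flagged (they are, if anything, strongly
    associated).  Returns (selected column names, flags dict).
    """
    y = np.asarray(trait, dtype=float)
    vals = y[~np.isnan(y)]
    if len(np.unique(vals)) < 2:
        raise ValueError("binary trait must have both classes present")
    selected, flags = [], {}
    for col in candidates.columns:
        x = candidates[col].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        X = np.column_stack([np.ones(ok.sum()), x[ok]])
        if len(np.unique(x[ok])) < 2:
            continue
        beta, cov, conv = _logistic_irls(X, y[ok])
        if not conv or cov is None:
            flags[col] = "separation"
            selected.append(col)
            continue
        se = np.sqrt(cov[1, 1])
        p = 2 * stats.norm.sf(abs(beta[1] / se)) if se > 0 else 0.0
        if p <= alpha:
            selected.append(col)
    return selected, flags


# ---------------------------------------------------------------------------
# Scans


def _class_counts(states, valid):
    s = states[valid]
    return int(np.sum(s == -1)), int(np.sum(s == 0)), int(np.sum(s == 1))


def _ols_many(x, Y):
    """Simple-regression slope/SE/p of each column of Y on x (with intercept).

    ``x`` may contain NaN (masked out); ``Y`` must be complete on the masked
    rows.  Returns (beta, se, p, n) arrays; degenerate x yields NaNs.
    """
    ok = ~np.isnan(x)
    x = x[ok]
    Y = Y[ok]
    n = x.size
    T = Y.shape[1]
    nan = np.full(T, np.nan)
    if n < 3:
        return nan, nan, nan, n
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        return nan, nan, nan, n
    ym = Y.mean(axis=0)
    sxy = xc @ Y
    beta = sxy / sxx
    syy = np.einsum("ij,ij->j", Y, Y) - n * ym**2
    rss = np.maximum(syy - beta * sxy, 0.0)
    dof = n - 2
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = np.maximum(2 * stats.t.sf(np.abs(tstat), dof), 5e-324)
    return beta, se, p, n


def linear_scan(matrix: CnvMatrix, model: str, traits) -> pd.DataFrame:
    """Linear association of residualised continuous trait(s) with each probe.

    ``traits`` is a Series (one trait) or DataFrame (trait per column) of
    covariate-corrected values aligned with ``matrix.sample_ids``.  Probes
    whose encoded dosage is degenerate (all one class, or fewer than three
    usable samples) yield a skipped-record row with ``skip_reason`` set.
    """
    model = canonical_model(model)
    if isinstance(traits, pd.Series):
        traits = traits.to_frame(traits.name or "trait")
    Y_full = traits.to_numpy(dtype=float)
    trait_names = list(traits.columns)
    y_missing = np.isnan(Y_full).any()

    rows = []
    crit = stats.norm.ppf(0.975)
    for i, probe in enumerate(matrix.probe_ids):
        states = matrix.states[i]
        dose = encode(states, model)
        if y_missing:
            # per-trait masks; loop (rare path)
            for t, name in enumerate(trait_names):
                yt = Y_full[:, t]
                m = ~np.isnan(yt)
                x_masked = np.where(m, dose, np.nan)
                b, se, p, n = _ols_many(x_masked, np.nan_to_num(yt)[:, None])
                rows.append(_lin_row(probe, matrix.probe_bp[i], name, model, states,
                                     ~np.isnan(dose) & m, b[0], se[0], p[0], crit))
        else:
            b, se, p, n = _ols_many(dose, Y_full)
            valid = ~np.isnan(dose)
            for t, name in enumerate(trait_names):
                rows.append(_lin_row(probe, matrix.probe_bp[i], name, model, states,
                                     valid, b[t], se[t], p[t], crit))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _lin_row(probe, bp, trait, model, states, valid, b, se, p, crit):
    n_del, n_neu, n_dup = _class_counts(states, valid)
    skip = None if np.isfinite(b) else "degenerate dosage"
    return {
        "probe_id": probe, "bp": int(bp), "trait": trait, "model": model,
        "effect": b, "se": se,
        "l95": b - crit * se if np.isfinite(b) else np.nan,
        "u95": b + crit * se if np.isfinite(b) else np.nan,
        "p": p, "n_del": n_del, "n_neutral": n_neu, "n_dup": n_dup,
        "fallback_flag": False, "skip_reason": skip,
    }


def logistic_scan(
    matrix: CnvMatrix,
    model: str,
    trait,
    covariates: pd.DataFrame | None = None,
    firth_fallback: bool = True,
) -> pd.DataFrame:
    """Logistic association of a binary trait with each probe's dosage.

    Effects are reported as odds ratios with Wald 95% CIs.  Fits falling
    back to the Firth penalty are flagged via ``fallback_flag``; probes with
    constant outcome or dosage among usable samples yield skipped records.
    """
    model = canonical_model(model)
    name = getattr(trait, "name", None) or "trait"
    y = np.asarray(trait, dtype=float)
    crit = stats.norm.ppf(0.975)
    rows = []
    for i, probe in enumerate(matrix.probe_ids):
        states = matrix.states[i]
        dose = encode(states, model)
        valid = ~np.isnan(dose) & ~np.isnan(y)
        if covariates is not None and covariates.shape[1]:
            valid &= ~covariates.isna().any(axis=1).to_numpy()
        n_del, n_neu, n_dup = _class_counts(states, valid)
        cases = y == 1
        base = {
            "probe_id": probe, "bp": int(matrix.probe_bp[i]), "trait": name,
            "model": model, "n_del": n_del, "n_neutral": n_neu, "n_dup": n_dup,
            "cases_del": int(np.sum(valid & cases & (states == -1))),
            "cases_neutral": int(np.sum(valid & cases & (states == 0))),
            "cases_dup": int(np.sum(valid & cases & (states == 1))),
        }
        fit = fit_logistic(
            dose, y,
            covariates.to_numpy(dtype=float) if covariates is not None and covariates.shape[1] else None,
            firth_fallback=firth_fallback,
        )
        if fit is None:
            rows.append({**base, "effect": np.nan, "se": np.nan, "l95": np.nan,
                         "u95": np.nan, "p": np.nan, "fallback_flag": False,
                         "skip_reason": "degenerate dosage or outcome"})
            continue
        b, se = fit["beta"], fit["se"]
        rows.append({**base, "effect": float(np.exp(b)), "se": se,
                     "l95": float(np.exp(b - crit * se)), "u95": float(np.exp(b + crit * se)),
                     "p": fit["p"], "fallback_flag": fit["fallback"], "skip_reason": None})
    cols = RESULT_COLUMNS + ["cases_del", "cases_neutral", "cases_dup"]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# Multiplicity


@dataclass
class MultiplicityResult:
    neff_probes: int
    neff_continuous: int
    neff_binary: int
    neff_total: int
    alpha: float


def effective_tests(corr: np.ndarray, var_fraction: float = 0.995) -> int:
    """Effective number of independent tests from a correlation matrix.

    The smallest m such that the m largest eigenvalues sum to at least
    ``var_fraction`` of the trace.  Perfectly correlated variables collapse
    to one effective test; uncorrelated variables count fully.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    ev = np.linalg.eigvalsh(corr)[::-1]
    ev = np.clip(ev, 0.0, None)
    target = var_fraction * ev.sum()
    csum = np.cumsum(ev)
    return int(np.searchsorted(csum, target - 1e-12) + 1)


def significance_threshold(
    neff_probes: int, neff_continuous: int, neff_binary: int, alpha_base: float = 0.05
) -> MultiplicityResult:
    """Combine per-axis effective test counts into the scan-wide threshold.

    ``N_eff = N_eff_probes * (N_eff_continuous + N_eff_binary)`` and
    ``alpha = alpha_base / N_eff``.
    """
    if neff_probes < 1 or neff_continuous < 0 or neff_binary < 0 or (neff_continuous + neff_binary) < 1:
        raise ValueError("effective counts must be positive")
    total = int(neff_probes) * (int(neff_continuous) + int(neff_binary))
    return MultiplicityResult(
        neff_probes=int(neff_probes),
        neff_continuous=int(neff_continuous),
        neff_binary=int(neff_binary),
        neff_total=total,
        alpha=alpha_base / total,
    )


def trait_correlation(traits: pd.DataFrame) -> np.ndarray:
    """Pairwise-complete Pearson correlation of trait columns (NaN -> 0)."""
    r = traits.corr(min_periods=2).to_numpy()
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


# ---------------------------------------------------------------------------
# Stepwise conditional analysis


def conditional_scan(
    matrix: CnvMatrix,
    model: str,
    trait,
    alpha: float,
    max_iter: int | None = None,
    condition: str = "mirror",
) -> pd.DataFrame:
    """Count independent signals by stepwise conditioning on lead probes.

    Iteratively: scan, take the minimum-p probe with p <= alpha as a lead,
    regress the lead probe's CNV status out of the (residual) trait, and
    rescan, until no probe passes.  Returns the ordered leads.

    ``condition`` chooses the encoding regressed out: ``"mirror"`` (default)
    removes the lead's raw copy-number state — the carried CNV status, not
    its model encoding; ``"carrier"`` removes separate deletion- and
    duplication-carrier indicators, which also exhausts U-shape signal at
    the lead.  The loop additionally stops when the same probe is re-elected
    lead (conditioning made no progress — the remaining signal at that probe
    is orthogonal to the conditioned encoding).
    """
    model = canonical_model(model)
    y = pd.Series(np.asarray(trait, dtype=float), name=getattr(trait, "name", "trait"))
    if max_iter is None:
        max_iter = matrix.n_probes
    leads = []
    seen = set()
    for step in range(1, max_iter + 1):
        res = linear_scan(matrix, model, y)
        res = res[res["skip_reason"].isna()]
        if not len(res) or res["p"].min() > alpha:
            break
        lead = res.loc[res["p"].idxmin()]
        if lead["probe_id"] in seen:
            break
        seen.add(lead["probe_id"])
        leads.append({"step": step, **lead[["probe_id", "bp", "effect", "se", "p"]].to_dict()})
        state = matrix.row(lead["probe_id"])
        filled = np.where(np.isnan(state), 0.0, state)
        if condition == "mirror":
            cond = pd.DataFrame({"lead": filled})
        elif condition == "carrier":
            cond = pd.DataFrame({"lead_del": (filled == -1).astype(float),
                                 "lead_dup": (filled == 1).astype(float)})
        else:
            raise ValueError("condition must be 'mirror' or 'carrier'")
        y = pd.Series(residualize_continuous(y, cond), name=y.name)
    return pd.DataFrame(leads, columns=["step", "probe_id", "bp", "effect", "se", "p"])


def burden_comparison(icd_counts, carrier_status):
    """Compare diagnosis burden of CNV carriers against copy-neutral samples.

    ``carrier_status`` holds −1/0/+1 per sample; returns two-sided Wilcoxon
    rank-sum p values ``(p_del, p_dup)`` for deletion-vs-neutral and
    duplication-vs-neutral; NaN when a group is empty.
    """
    from .sensitivity import wilcoxon_rank_sum

    counts = np.asarray(icd_counts, dtype=float)
    status = np.asarray(carrier_status, dtype=float)
    neutral = counts[status == 0]
    out = []
    for cls in (-1, 1):
        grp = counts[status == cls]
        if grp.size == 0 or neutral.size == 0:
            out.append(np.nan)
        else:
            out.append(wilcoxon_rank_sum(grp, neutral, alternative="two-sided"))
    return tuple(out)
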