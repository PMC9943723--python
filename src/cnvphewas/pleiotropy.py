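"""Vertical-vs-horizontal pleiotropy decomposition and concordance checks.

If a CNV's association with an outcome trait is mediated by an exposure
trait (vertical pleiotropy), the CNV effect on the outcome expected from
the causal chain is the product of the CNV effect on the exposure (mirror
model, best probe) and the exposure→outcome causal estimate from IVW MR:
``beta_expected = beta_exposure * beta_IVW``.  Comparing it with the CNV
effect observed directly on the outcome distinguishes mediated effects from
genuine horizontal pleiotropy.  Directional concordance between TWMR and
mirror-scan effects is summarised with a weighted zero-intercept regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PleiotropyPair:
    exposure: str
    outcome: str
    beta_exposure: float
    se_exposure: float
    beta_ivw: float
    se_ivw: float
    beta_observed: float
    se_observed: float

    @property
    def beta_expected(self) -> float:
        return self.beta_exposure * self.beta_ivw

    @property
    def se_expected(self) -> float:
        return expected_outcome_effect(self.beta_exposure, self.se_exposure,
                                       self.beta_ivw, self.se_ivw)[1]


def expected_outcome_effect(beta_exposure: float, se_exposure: float,
                            beta_ivw: float, se_ivw: float):
    """Expected CNV effect on the outcome under pure mediation.

    Point estimate ``beta_exposure * beta_ivw``; SE by first-order (delta
    method) propagation assuming independent inputs:
    ``sqrt(beta_exp² se_ivw² + beta_ivw² se_exp²)``.
    """
    if not (np.isfinite(beta_exposure) and np.isfinite(beta_ivw)):
        raise ValueError("effects must be finite")
    est = beta_exposure * beta_ivw
    se = float(np.sqrt(beta_exposure**2 * se_ivw**2 + beta_ivw**2 * se_exposure**2))
    return float(est), se


def classify_pair(pair: PleiotropyPair, mode: str = "ci") -> dict:
    """Classify one exposure-outcome pair as vertical-consistent or not.

    ``ci`` mode (default diagnostic): vertical-consistent iff the expected
    and observed effects agree in sign and either point estimate falls
    inside the other's 95% CI.  ``sign`` mode uses sign agreement only.
    """
    expected, se_exp = expected_outcome_effect(
        pair.beta_exposure, pair.se_exposure, pair.beta_ivw, pair.se_ivw
    )
    obs, se_obs = pair.beta_observed, pair.se_observed
    signs_agree = np.sign(expected) == np.sign(obs) and expected != 0
    crit = stats.norm.ppf(0.975)
    flagged = False
    if mode == "sign" or not (np.isfinite(se_exp) and np.isfinite(se_obs)):
        vertical = bool(signs_agree)
        flagged = mode != "sign"  # CI requested but unavailable
    else:
        in_obs_ci = obs - crit * se_obs <= expected <= obs + crit * se_obs
        in_exp_ci = expected - crit * se_exp <= obs <= expected + crit * se_exp
        vertical = bool(signs_agree and (in_obs_ci or in_exp_ci))
    return {
        "exposure": pair.exposure, "outcome": pair.outcome,
        "beta_expected": expected, "se_expected": se_exp,
        "beta_observed": obs, "se_observed": se_obs,
        "signs_agree": bool(signs_agree),
        "verdict": "vertical-consistent" if vertical else "horizontal-suggestive",
        "sign_only": flagged,
    }


def zero_intercept_regression(x, y, weights=None):
    """Weighted least-squares line through the origin.

    slope = sum(w x y) / sum(w x²); SE from the weighted residual variance;
    Wald t test for slope ≠ 0 on n−1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    sxx = float(np.sum(w * x**2))
    if sxx == 0:
        raise ValueError("all x are zero; slope undefined")
    slope = float(np.sum(w * x * y) / sxx)
    resid = y - slope * x
    dof = x.size - 1
    sigma2 = float(np.sum(w * resid**2) / dof)
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0:
        return slope, 0.0, 5e-324
    t = slope / se
    p = float(max(2 * stats.t.sf(abs(t), dof), 5e-324))
    return slope, se, p


def _best_probe(scan: pd.DataFrame, lo: int, hi: int, trait: str, p_max: float = 0.05):
    """Minimum-p nominally significant mirror probe in [lo, hi]; ties by bp."""
    sub = scan[(scan["trait"] == trait) & (scan["bp"] >= lo) & (scan["bp"] <= hi)
               & scan["p"].notna() & (scan["p"] < p_max)]
    if not len(sub):
        return None
    return sub.sort_values(["p", "bp"], kind="mergesort").iloc[0]


def twmr_scan_concordance(twmr_results: pd.DataFrame, mirror_scan: pd.DataFrame,
                          gene_annotation: pd.DataFrame, window: int = 10_000,
                          p_max: float = 0.05) -> dict:
    """Directional concordance between TWMR and mirror-scan effects.

    ``twmr_results`` holds (gene, trait/outcome, beta, se, p); for every
    nominally significant TWMR estimate the minimum-p nominally significant
    mirror probe within the gene ± ``window`` is paired with it; agreement
    is sign match, and a weighted (1/se_scan²) zero-intercept regression of
    scan beta on TWMR beta summarises the relationship.
    """
    ann = gene_annotation.set_index("gene")
    points = []
    for rec in twmr_results.itertuples(index=False):
        if not np.isfinite(rec.p) or rec.p >= p_max:
            continue
        if rec.gene not in ann.index:
            continue
        lo = int(ann.loc[rec.gene, "start"]) - window
        hi = int(ann.loc[rec.gene, "end"]) + window
        probe = _best_probe(mirror_scan, lo, hi, rec.outcome, p_max)
        if probe is None:
            continue
        points.append({
            "gene": rec.gene, "trait": rec.outcome,
            "twmr_beta": rec.beta, "twmr_se": rec.se,
            "mirror_beta": probe["effect"], "mirror_se": probe["se"],
            "probe_id": probe["probe_id"],
            "agree": bool(np.sign(rec.beta) == np.sign(probe["effect"])),
        })
    pts = pd.DataFrame(points, columns=["gene", "trait", "twmr_beta", "twmr_se",
                                        "mirror_beta", "mirror_se", "probe_id", "agree"])
    summary = {"n_pairs": len(pts), "n_agree": int(pts["agree"].sum()) if len(pts) else 0,
               "slope": float("nan"), "se": float("nan"), "p": float("nan")}
    if len(pts) >= 2 and np.any(pts["twmr_beta"] != 0):
        slope, se, p = zero_intercept_regression(
            pts["twmr_beta"], pts["mirror_beta"], weights=1.0 / pts["mirror_se"]**2
        )
        summary.update(slope=slope, se=se, p=p)
    return {"points": pts, "summary": summary}


def decompose_pleiotropy(pairs: list, mode: str = "sign") -> pd.DataFrame:
    """Classify a collection of exposure-outcome pairs; see classify_pair."""
    return pd.DataFrame([classify_pair(p, mode=mode) for p in pairs])
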