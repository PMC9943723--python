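"""Two-sample summary-statistic Mendelian randomization.

Exposure (eQTL or GWAS) and outcome summary statistics are harmonized to a
common effect allele (palindromic SNPs and allele-frequency-discordant SNPs
removed), pruned to independent instruments by greedy LD clumping, screened
for reverse causation with Steiger filtering, and combined into a causal
estimate by fixed-effect inverse-variance weighting (IVW).  Multivariable
MR (MVMR) jointly regresses outcome effects on several exposures' effects
to separate direct from mediated causal paths.

Bookkeeping conventions follow the published analysis: transcriptome-wide
MR (TWMR) requires at least 5 independent instruments per transcript and a
Bonferroni threshold of 0.05 over the number of transcripts tested; the
cross-trait MVMR threshold divides 0.05 by the square of the number of
traits (all ordered exposure-outcome combinations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SUMSTAT_COLUMNS = ["snp_id", "chrom", "bp", "effect_allele", "other_allele",
                   "eaf", "beta", "se", "pval", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_MIN_IVS = 5
DEFAULT_STEIGER_ALPHA = 5e-3
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_TWMR_IV_R2 = 0.01
DEFAULT_MAF_MIN = 0.01
DEFAULT_MAX_AF_DIFF = 0.05


@dataclass
class MrEstimate:
    exposure: str
    outcome: str
    method: str
    n_ivs: int
    beta: float | None
    se: float | None
    p: float | None
    steiger_removed: int = 0
    withheld_reason: str | None = None


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G allele pairs cannot be strand-resolved from alleles alone."""
    return _COMPLEMENT.get(str(a1).upper()) == str(a2).upper()


# ---------------------------------------------------------------------------
# Harmonization


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              max_af_diff: float = DEFAULT_MAX_AF_DIFF) -> pd.DataFrame:
    """Align outcome records to each exposure SNP's effect allele.

    Keeps SNPs present in both tables; flips the outcome beta's sign and
    complements its allele frequency when the outcome is reported on the
    swapped allele pair; drops palindromic SNPs, SNPs with irreconcilable
    alleles, and SNPs whose post-alignment allele-frequency difference
    exceeds ``max_af_diff``.  Returns the harmonized pair table; running it
    again on its own output is a no-op.
    """
    merged = exposure.merge(outcome, on="snp_id", suffixes=("_exp", "_out"))
    rows = []
    for rec in merged.itertuples(index=False):
        ea_e, oa_e = str(rec.effect_allele_exp).upper(), str(rec.other_allele_exp).upper()
        ea_o, oa_o = str(rec.effect_allele_out).upper(), str(rec.other_allele_out).upper()
        if is_palindromic(ea_e, oa_e):
            continue
        if (ea_o, oa_o) == (ea_e, oa_e):
            beta_out, eaf_out = rec.beta_out, rec.eaf_out
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_out, eaf_out = -rec.beta_out, 1.0 - rec.eaf_out
        else:
            continue  # irreconcilable allele sets
        if np.isfinite(rec.eaf_exp) and np.isfinite(eaf_out) and abs(rec.eaf_exp - eaf_out) > max_af_diff:
            continue
        rows.append({
            "snp_id": rec.snp_id,
            "effect_allele": ea_e, "other_allele": oa_e,
            "eaf_exp": rec.eaf_exp, "eaf_out": eaf_out,
            "beta_exp": rec.beta_exp, "se_exp": rec.se_exp,
            "beta_out": beta_out, "se_out": rec.se_out,
            "n_exp": getattr(rec, "n_exp", np.nan),
            "n_out": getattr(rec, "n_out", np.nan),
        })
    return pd.DataFrame(rows, columns=["snp_id", "effect_allele", "other_allele",
                                       "eaf_exp", "eaf_out", "beta_exp", "se_exp",
                                       "beta_out", "se_out", "n_exp", "n_out"])


def pairs_to_records(pairs: pd.DataFrame, side: str) -> pd.DataFrame:
    """Re-express one side of a harmonized pair table as summary-stat records."""
    suffix = {"exposure": "exp", "outcome": "out"}[side]
    return pd.DataFrame({
        "snp_id": pairs["snp_id"],
        "chrom": "NA", "bp": 0,
        "effect_allele": pairs["effect_allele"],
        "other_allele": pairs["other_allele"],
        "eaf": pairs[f"eaf_{suffix}"],
        "beta": pairs[f"beta_{suffix}"],
        "se": pairs[f"se_{suffix}"],
        "pval": 2 * stats.norm.sf(np.abs(pairs[f"beta_{suffix}"] / pairs[f"se_{suffix}"])),
        "n": pairs[f"n_{suffix}"],
    })


# ---------------------------------------------------------------------------
# LD clumping


def clump(records: pd.DataFrame, ld: pd.DataFrame,
          r2_max: float = DEFAULT_CLUMP_R2, maf_min: float = DEFAULT_MAF_MIN) -> list:
    """Greedy p-value-ordered LD clumping after a MAF filter.

    ``ld`` is a square r² (or r; squared internally if signed) matrix indexed
    by SNP id.  SNPs with MAF <= ``maf_min`` are removed first; remaining
    SNPs are visited by ascending p and kept unless in LD (r² > ``r2_max``)
    with an already kept SNP.  SNPs absent from the LD matrix are treated as
    independent.  Returns the kept SNP ids in selection order.
    """
    df = records.copy()
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    df = df[maf > maf_min]
    df = df.sort_values(["pval", "snp_id"], kind="mergesort")
    ld_vals = ld.to_numpy(dtype=float)
    if np.nanmin(ld_vals) < 0:  # signed r supplied
        ld = ld**2
    kept = []
    for rec in df.itertuples(index=False):
        snp = rec.snp_id
        if snp not in ld.index:
            kept.append(snp)
            continue
        in_ld = False
        for k in kept:
            if k in ld.columns and ld.loc[snp, k] > r2_max:
                in_ld = True
                break
        if not in_ld:
            kept.append(snp)
    return kept


# ---------------------------------------------------------------------------
# Estimators


def ivw(pairs: pd.DataFrame, min_ivs: int = DEFAULT_MIN_IVS,
        exposure: str = "exposure", outcome: str = "outcome") -> MrEstimate:
    """Fixed-effect inverse-variance weighted causal estimate.

    alpha_hat = sum(w * b_exp * b_out) / sum(w * b_exp^2) with
    w = 1/se_out^2; SE = (sum w b_exp^2)^{-1/2}; Wald p.  Estimates from
    fewer than ``min_ivs`` instruments are withheld.
    """
    k = len(pairs)
    if k < min_ivs:
        return MrEstimate(exposure, outcome, "IVW", k, None, None, None,
                          withheld_reason=f"{k} IVs < required {min_ivs}")
    bx = pairs["beta_exp"].to_numpy(dtype=float)
    by = pairs["beta_out"].to_numpy(dtype=float)
    w = 1.0 / pairs["se_out"].to_numpy(dtype=float) ** 2
    denom = float(np.sum(w * bx**2))
    if denom <= 0:
        return MrEstimate(exposure, outcome, "IVW", k, None, None, None,
                          withheld_reason="zero exposure signal")
    alpha = float(np.sum(w * bx * by) / denom)
    se = float(denom ** -0.5)
    p = float(max(2 * stats.norm.sf(abs(alpha / se)), 5e-324))
    return MrEstimate(exposure, outcome, "IVW", k, alpha, se, p)


def variance_explained(beta, eaf) -> np.ndarray:
    """Per-SNP trait variance explained by a standardized per-allele effect."""
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    return 2.0 * eaf * (1.0 - eaf) * beta**2


def steiger_filter(pairs: pd.DataFrame, n_exposure=None, n_outcome=None,
                   alpha: float = DEFAULT_STEIGER_ALPHA) -> pd.DataFrame:
    """Drop instruments that explain significantly more outcome than exposure.

    Variance explained is 2*eaf*(1-eaf)*beta² per side; the implied
    correlations are compared on the Fisher z scale with the two sample
    sizes.  An IV is removed when r²_out > r²_exp and the one-sided
    directionality p falls below ``alpha``.  IVs with missing allele
    frequency are retained and flagged untested.
    """
    df = pairs.copy()
    n_exp = df["n_exp"] if n_exposure is None else pd.Series(n_exposure, index=df.index, dtype=float)
    n_out = df["n_out"] if n_outcome is None else pd.Series(n_outcome, index=df.index, dtype=float)
    keep = np.ones(len(df), dtype=bool)
    untested = np.zeros(len(df), dtype=bool)
    for i, (idx, rec) in enumerate(df.iterrows()):
        eaf = rec["eaf_exp"]
        if not np.isfinite(eaf) or not (np.isfinite(n_exp[idx]) and np.isfinite(n_out[idx])):
            untested[i] = True
            continue
        r2e = float(variance_explained(rec["beta_exp"], eaf))
        r2o = float(variance_explained(rec["beta_out"], eaf))
        if r2o <= r2e:
            continue
        re_, ro = np.sqrt(min(r2e, 1 - 1e-12)), np.sqrt(min(r2o, 1 - 1e-12))
        z = (np.arctanh(ro) - np.arctanh(re_)) / np.sqrt(
            1.0 / (n_out[idx] - 3) + 1.0 / (n_exp[idx] - 3)
        )
        if stats.norm.sf(z) < alpha:
            keep[i] = False
    out = df[keep].copy()
    out["steiger_untested"] = untested[keep]
    return out


def mvmr(outcome_beta, outcome_se, exposure_betas: pd.DataFrame,
         outcome: str = "outcome") -> list:
    """Multivariable MR: weighted no-intercept regression on exposure effects.

    ``exposure_betas`` has one column per exposure, one row per IV; the
    outcome betas are regressed on all columns jointly with weights
    1/se_out², yielding each exposure's direct effect conditional on the
    others.  Raises on rank deficiency, naming the collinear exposures.
    """
    B = exposure_betas.to_numpy(dtype=float)
    y = np.asarray(outcome_beta, dtype=float)
    se = np.asarray(outcome_se, dtype=float)
    m, k = B.shape
    if m < k + 1:
        raise ValueError(f"need at least {k + 1} IVs for {k} exposures, got {m}")
    if np.linalg.matrix_rank(B) < k:
        cols = list(exposure_betas.columns)
        cc = np.corrcoef(B.T)
        pairs = [(cols[i], cols[j]) for i in range(k) for j in range(i + 1, k)
                 if abs(cc[i, j]) > 1 - 1e-10]
        raise ValueError(f"collinear exposures: {pairs or cols}")
    w = 1.0 / se**2
    XtW = B.T * w
    cov = np.linalg.inv(XtW @ B)
    theta = cov @ (XtW @ y)
    ses = np.sqrt(np.diag(cov))
    out = []
    for j, name in enumerate(exposure_betas.columns):
        z = theta[j] / ses[j]
        out.append(MrEstimate(str(name), outcome, "MVMR", m, float(theta[j]),
                              float(ses[j]), float(max(2 * stats.norm.sf(abs(z)), 5e-324))))
    return out


# ---------------------------------------------------------------------------
# Pipelines and bookkeeping


def twmr_pipeline(gene: str, eqtl: pd.DataFrame, gwas: pd.DataFrame, ld: pd.DataFrame,
                  outcome: str = "outcome",
                  iv_r2: float = DEFAULT_TWMR_IV_R2,
                  maf_min: float = DEFAULT_MAF_MIN,
                  max_af_diff: float = DEFAULT_MAX_AF_DIFF,
                  steiger_alpha: float = DEFAULT_STEIGER_ALPHA,
                  min_ivs: int = DEFAULT_MIN_IVS,
                  steiger: bool = True) -> MrEstimate:
    """Transcript-level causal effect of gene expression on a trait.

    Chains harmonization, LD pruning of instruments (r² < ``iv_r2``),
    Steiger directionality filtering and fixed-effect IVW.  Estimates with
    fewer than ``min_ivs`` surviving instruments are withheld.
    """
    pairs = harmonize(eqtl, gwas, max_af_diff=max_af_diff)
    if len(pairs):
        exp_records = pairs_to_records(pairs, "exposure")
        kept = clump(exp_records, ld, r2_max=iv_r2, maf_min=maf_min)
        pairs = pairs[pairs["snp_id"].isin(kept)]
    n_before = len(pairs)
    if steiger and len(pairs):
        pairs = steiger_filter(pairs, alpha=steiger_alpha)
    est = ivw(pairs, min_ivs=min_ivs, exposure=gene, outcome=outcome)
    est.steiger_removed = n_before - len(pairs)
    return est


def twmr_significance_threshold(n_genes_tested: int, alpha_base: float = 0.05) -> float:
    """Bonferroni threshold across the transcripts carried to TWMR."""
    if n_genes_tested < 1:
        raise ValueError("need at least one tested gene")
    return alpha_base / n_genes_tested


def mvmr_test_count(n_traits: int) -> int:
    """Number of exposure-outcome combinations among n traits (n², the
    published bookkeeping counts all ordered combinations)."""
    if n_traits < 1:
        raise ValueError("need at least one trait")
    return n_traits * n_traits


def mvmr_significance_threshold(n_traits: int, alpha_base: float = 0.05) -> float:
    """Bonferroni threshold over all exposure-outcome combinations."""
    return alpha_base / mvmr_test_count(n_traits)
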