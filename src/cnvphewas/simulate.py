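"""Synthetic data emulating a region-focused CNV phenome-wide scan.

Generates every input the pipeline consumes: low-frequency CNV calls with
low-copy-repeat (LCR) anchored breakpoints and quality scores, a probe map
over the focal region, phenotypes with effects planted under any of the four
dosage models on top of realistic covariate structure, and two-sample MR
summary statistics with planted causal effects, horizontal pleiotropy,
palindromic SNPs, allele-frequency mismatches and reverse-causal
instruments.  Identical configuration (including seed) reproduces outputs
bit for bit.

Default carrier frequencies are inflated roughly tenfold over the published
population frequencies so that planted effects are recoverable at simulated
cohort sizes; ``population_frequencies()`` restores the population-scale rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .cnv_matrix import CALL_COLUMNS
from .dosage import canonical_model
from .mr import SUMSTAT_COLUMNS

REGION_START = 18_630_000
REGION_END = 21_910_000

#: LCR A-D intervals (bp) anchoring recurrent rearrangements in the region.
DEFAULT_LCR_POSITIONS = {
    "A": (18_630_000, 18_930_000),
    "B": (20_130_000, 20_430_000),
    "C": (20_720_000, 20_820_000),
    "D": (21_610_000, 21_910_000),
}

#: Published population carrier frequencies by LCR category and CNV type.
_POPULATION_FREQS = {
    "A-B": {"dup": 0.0001, "del": 0.00002},
    "A-D": {"dup": 0.0006, "del": 0.00001},
    "B-D": {"dup": 0.00002, "del": 0.0},
    "C-D": {"dup": 0.0004, "del": 0.00008},
    "atypical": {"dup": 0.0016, "del": 0.0016},
}


def population_frequencies() -> dict:
    """Population-scale carrier frequencies (percent-scale rarities)."""
    return {k: dict(v) for k, v in _POPULATION_FREQS.items()}


def default_frequencies() -> dict:
    """Test-power frequencies: published rates inflated tenfold."""
    return {k: {t: 10 * f for t, f in v.items()} for k, v in _POPULATION_FREQS.items()}


@dataclass
class PlantedEffect:
    """One trait with a known CNV effect planted under a dosage model."""

    trait_name: str
    trait_kind: str  # continuous | binary
    model: str
    effect_size: float  # trait-SD units (continuous) or log-odds (binary)
    target_interval: tuple  # (start_bp, end_bp) of probes carrying the effect
    prevalence: float = 0.1  # binary traits only

    def __post_init__(self):
        self.model = canonical_model(self.model)
        if self.trait_kind not in ("continuous", "binary"):
            raise ValueError("trait_kind must be 'continuous' or 'binary'")


@dataclass
class MrSpec:
    """Parameters of the summary-statistic simulation."""

    genes: tuple = ("GENE1", "GENE2", "GENE3")
    n_ivs: int = 20
    # published transcript-to-trait causal effects are of order 0.05 trait SD
    # per expression SD; at this scale the exposure-side sampling noise is
    # negligible next to the outcome noise and fixed-effect IVW CIs are valid
    causal_effect: float = 0.05  # exposure -> outcome effect alpha
    pleiotropy_frac: float = 0.0
    pleiotropy_sd: float = 0.05
    reverse_frac: float = 0.0
    palindromic_frac: float = 0.0
    af_mismatch_frac: float = 0.0
    allele_swap_frac: float = 0.2  # outcome reported on swapped alleles
    noise_scale: float = 1.0  # multiplier on sampling noise (0 = noiseless betas)
    n_exposure: int = 30_000
    n_outcome: int = 300_000


@dataclass
class CovariateSpec:
    age_range: tuple = (40.0, 69.0)
    n_batches: int = 4
    n_pcs: int = 10


@dataclass
class SimConfig:
    n_samples: int = 20_000
    region_start: int = REGION_START
    region_end: int = REGION_END
    lcr_positions: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_LCR_POSITIONS.items()})
    n_probes: int = 864
    cnv_class_freqs: dict = field(default_factory=default_frequencies)
    qs_beta_a: float = 5.0
    qs_beta_b: float = 1.0
    qs_low_frac: float = 0.05  # fraction of calls drawn below the 0.5 retention bar
    breakpoint_jitter: int = 20_000
    allow_multi_call: bool = False
    planted_effects: list = field(default_factory=list)
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    mr_spec: MrSpec = field(default_factory=MrSpec)
    seed: int = 0

    def __post_init__(self):
        for typ in ("dup", "del"):
            total = sum(v.get(typ, 0.0) for v in self.cnv_class_freqs.values())
            if total > 1.0:
                raise ValueError(f"{typ} frequencies sum to {total} > 1")
            for cat, v in self.cnv_class_freqs.items():
                f = v.get(typ, 0.0)
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"frequency out of [0,1] for {cat}/{typ}")
        order = [self.lcr_positions[k][0] for k in "ABCD"]
        if order != sorted(order):
            raise ValueError("LCR intervals must be ordered A < B < C < D")
        for k in "ABCD":
            lo, hi = self.lcr_positions[k]
            if not (self.region_start <= lo <= hi <= self.region_end):
                raise ValueError(f"LCR {k} outside the region")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-purpose random substream."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


_STREAM_CALLS, _STREAM_PHENO, _STREAM_MR, _STREAM_PROBES = 1, 2, 3, 4


# ---------------------------------------------------------------------------
# Probe map and CNV calls


def simulate_probe_map(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced probes across the region (BIM-like: chrom, id, bp)."""
    bp = np.linspace(config.region_start, config.region_end, config.n_probes)
    bp = np.unique(np.round(bp).astype(np.int64))
    return pd.DataFrame({
        "chrom": "22",
        "probe_id": [f"probe{i:04d}" for i in range(len(bp))],
        "cm": 0,
        "bp": bp,
    })


def sample_ids(config: SimConfig) -> list:
    return [f"S{i:06d}" for i in range(config.n_samples)]


def simulate_cnv_calls(config: SimConfig) -> pd.DataFrame:
    """Draw carriers per LCR category and emit one CNV call each.

    Carrier counts are binomial at the configured per-category frequencies;
    breakpoints sit at the flanking LCR boundaries with uniform jitter
    (atypical calls get uniform random spans).  |QS| follows Beta(a, b)
    signed by call type (deletions negative), with a configured fraction
    replaced by draws below the 0.5 retention threshold.
    """
    rng = config.rng(_STREAM_CALLS)
    ids = np.array(sample_ids(config))
    available = np.ones(config.n_samples, dtype=bool)
    j = config.breakpoint_jitter
    rows = []
    for cat in sorted(config.cnv_class_freqs):
        for typ in ("dup", "del"):
            freq = config.cnv_class_freqs[cat].get(typ, 0.0)
            if freq <= 0:
                continue
            n_carriers = rng.binomial(config.n_samples, freq)
            if n_carriers == 0:
                continue
            pool = np.flatnonzero(available) if not config.allow_multi_call else np.arange(config.n_samples)
            n_carriers = min(n_carriers, pool.size)
            chosen = rng.choice(pool, size=n_carriers, replace=False)
            if not config.allow_multi_call:
                available[chosen] = False
            for idx in chosen:
                if cat == "atypical":
                    length = int(rng.uniform(80_000, 2_000_000))
                    start = int(rng.uniform(config.region_start, config.region_end - length))
                    end = start + length
                else:
                    x, y = cat.split("-")
                    start = config.lcr_positions[x][0]
                    end = config.lcr_positions[y][1]
                    if j > 0:
                        start += int(rng.integers(-j, j + 1))
                        end += int(rng.integers(-j, j + 1))
                qs_mag = rng.beta(config.qs_beta_a, config.qs_beta_b)
                if rng.uniform() < config.qs_low_frac:
                    qs_mag = rng.uniform(0.0, 0.5)
                qs = qs_mag if typ == "dup" else -qs_mag
                rows.append({"sample_id": ids[idx], "chrom": "22",
                             "start": int(start), "end": int(end),
                             "cn_class": typ, "qs": float(qs), "category": cat})
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS + ["category"])
    return calls.sort_values(["sample_id", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Phenotypes


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    rng = config.rng(_STREAM_PHENO)
    n = config.n_samples
    spec = config.covariate_spec
    cov = {"age": rng.uniform(*spec.age_range, size=n).round(1)}
    cov["age2"] = cov["age"] ** 2
    cov["sex"] = rng.integers(0, 2, size=n).astype(float)
    batch = rng.integers(0, spec.n_batches, size=n)
    for b in range(1, spec.n_batches):
        cov[f"batch_{b}"] = (batch == b).astype(float)
    for k in range(1, spec.n_pcs + 1):
        cov[f"pc{k}"] = rng.standard_normal(n)
    return pd.DataFrame(cov, index=sample_ids(config))


def interval_states(matrix, interval) -> np.ndarray:
    """Per-sample CNV genotype over a target interval.

    Any deletion probe in the interval marks the sample a deletion carrier;
    otherwise any duplication probe marks a duplication carrier; otherwise
    neutral.  Calls are contiguous, so states within an interval agree.
    """
    lo, hi = interval
    mask = (matrix.probe_bp >= lo) & (matrix.probe_bp <= hi)
    if not mask.any():
        raise ValueError(f"target interval {interval} covers no probe")
    sub = matrix.states[mask]
    has_del = np.any(sub == -1, axis=0)
    has_dup = np.any(sub == 1, axis=0)
    return np.where(has_del, -1.0, np.where(has_dup, 1.0, 0.0))


def _genetic_value(states: np.ndarray, model: str) -> np.ndarray:
    model = canonical_model(model)
    if model == "mirror":
        return states
    if model == "deletion-only":
        return (states == -1).astype(float)
    if model == "duplication-only":
        return (states == 1).astype(float)
    return (np.abs(states) == 1).astype(float)


def simulate_phenotypes(config: SimConfig, matrix, covariates: pd.DataFrame | None = None):
    """Generate trait + covariate table with the configured planted effects.

    Continuous traits: covariate linear predictor + effect_size x encoded
    dosage + standard normal noise.  Binary traits: Bernoulli through a
    logistic link at the configured prevalence, shifted by effect_size
    (log-odds) times the encoded dosage.  Traits with effect_size 0 are
    exact nulls.  Returns (phenotype DataFrame, ground-truth dict).
    """
    if list(matrix.sample_ids) != sample_ids(config):
        raise ValueError("matrix samples do not match config")
    rng = config.rng(_STREAM_PHENO + 100)
    if covariates is None:
        covariates = simulate_covariates(config)
    n = config.n_samples

    # fixed, seed-determined covariate effects on every trait
    cov_std = (covariates - covariates.mean()) / covariates.std().replace(0, 1)
    coefs = rng.normal(0.0, 0.15, size=cov_std.shape[1])
    lp_cov = cov_std.to_numpy() @ coefs

    pheno = covariates.copy()
    truth = {}
    for eff in config.planted_effects:
        states = interval_states(matrix, eff.target_interval)
        g = _genetic_value(states, eff.model)
        if eff.trait_kind == "continuous":
            y = lp_cov + eff.effect_size * g + rng.standard_normal(n)
        else:
            eta = special.logit(eff.prevalence) + 0.5 * lp_cov + eff.effect_size * g
            y = (rng.uniform(size=n) < special.expit(eta)).astype(float)
        pheno[eff.trait_name] = y
        truth[eff.trait_name] = {
            "model": eff.model, "effect_size": eff.effect_size,
            "trait_kind": eff.trait_kind,
            "target_interval": list(eff.target_interval),
            "n_del": int(np.sum(states == -1)), "n_dup": int(np.sum(states == 1)),
        }
    pheno.index.name = "sample_id"
    return pheno, truth


def simulate_null_traits(n_samples: int, n_traits: int, seed: int = 0,
                         binary_prevalence: float | None = None) -> pd.DataFrame:
    """Pure-null traits (standard normal, or Bernoulli when a prevalence is
    given) for calibration experiments."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
    if binary_prevalence is None:
        vals = rng.standard_normal((n_samples, n_traits))
    else:
        vals = (rng.uniform(size=(n_samples, n_traits)) < binary_prevalence).astype(float)
    return pd.DataFrame(vals, columns=[f"null{i:04d}" for i in range(n_traits)])


# ---------------------------------------------------------------------------
# Summary statistics for MR


_NONPALINDROMIC = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                   ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def simulate_summary_stats(config: SimConfig, outcome: str = "outcome"):
    """Simulate eQTL + outcome GWAS summary statistics per gene.

    For each gene, ``n_ivs`` independent instruments receive true exposure
    effects; outcome effects are ``alpha x exposure effect`` plus horizontal
    pleiotropy for the configured fraction, with sampling noise consistent
    with the stated sample sizes.  Configured fractions of palindromic
    SNPs, allele-frequency-mismatched SNPs, allele-swapped outcome records
    and reverse-causal instruments are injected and recorded in the
    returned ground truth.

    Returns ``(eqtl, gwas, ld, truth)``: two summary-stat tables (the eQTL
    table has a ``gene`` column), an identity LD matrix over all SNPs, and
    the truth dict (true alpha and injected-SNP lists).
    """
    spec = config.mr_spec
    if spec.n_ivs < 1:
        raise ValueError("n_ivs must be >= 1")
    rng = config.rng(_STREAM_MR)
    eqtl_rows, gwas_rows = [], []
    truth = {"alpha": {}, "palindromic": [], "af_mismatch": [], "reverse": [],
             "swapped": []}
    for gi, gene in enumerate(spec.genes):
        alpha = spec.causal_effect if np.isscalar(spec.causal_effect) else spec.causal_effect[gi]
        truth["alpha"][gene] = float(alpha)
        for i in range(spec.n_ivs):
            snp = f"{gene}_iv{i:03d}"
            eaf = float(rng.uniform(0.05, 0.95))
            bx_true = float(rng.choice([-1, 1]) * rng.uniform(0.05, 0.2))
            by_true = alpha * bx_true
            u = rng.uniform()
            if u < spec.reverse_frac:
                # outcome-first variant: big outcome effect, tiny exposure one
                bx_true = float(rng.choice([-1, 1]) * rng.uniform(0.001, 0.005))
                by_true = float(rng.choice([-1, 1]) * rng.uniform(0.1, 0.2))
                truth["reverse"].append(snp)
            elif rng.uniform() < spec.pleiotropy_frac:
                by_true += float(rng.normal(0.0, spec.pleiotropy_sd))
            se_x = float(1.0 / np.sqrt(2 * eaf * (1 - eaf) * spec.n_exposure))
            se_y = float(1.0 / np.sqrt(2 * eaf * (1 - eaf) * spec.n_outcome))
            bx = bx_true + spec.noise_scale * float(rng.normal(0.0, se_x))
            by = by_true + spec.noise_scale * float(rng.normal(0.0, se_y))
            if rng.uniform() < spec.palindromic_frac:
                ea, oa = _PALINDROMIC[rng.integers(len(_PALINDROMIC))]
                truth["palindromic"].append(snp)
            else:
                ea, oa = _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
            eaf_out = eaf
            if rng.uniform() < spec.af_mismatch_frac:
                shift = float(rng.choice([-1, 1]) * rng.uniform(0.06, 0.2))
                eaf_out = float(np.clip(eaf + shift, 0.01, 0.99))
                truth["af_mismatch"].append(snp)
            bp = 1_000_000 * (gi + 1) + i
            eqtl_rows.append({"snp_id": snp, "chrom": "22", "bp": bp,
                              "effect_allele": ea, "other_allele": oa, "eaf": eaf,
                              "beta": bx, "se": se_x,
                              "pval": float(2 * stats.norm.sf(abs(bx / se_x))),
                              "n": spec.n_exposure, "gene": gene})
            if rng.uniform() < spec.allele_swap_frac:
                g_ea, g_oa, g_beta, g_eaf = oa, ea, -by, 1 - eaf_out
                truth["swapped"].append(snp)
            else:
                g_ea, g_oa, g_beta, g_eaf = ea, oa, by, eaf_out
            gwas_rows.append({"snp_id": snp, "chrom": "22", "bp": bp,
                              "effect_allele": g_ea, "other_allele": g_oa,
                              "eaf": g_eaf, "beta": g_beta, "se": se_y,
                              "pval": float(2 * stats.norm.sf(abs(g_beta / se_y))),
                              "n": spec.n_outcome})
    eqtl = pd.DataFrame(eqtl_rows, columns=SUMSTAT_COLUMNS + ["gene"])
    gwas = pd.DataFrame(gwas_rows, columns=SUMSTAT_COLUMNS)
    snps = list(eqtl["snp_id"])
    ld = pd.DataFrame(np.eye(len(snps)), index=snps, columns=snps)
    return eqtl, gwas, ld, truth


# ---------------------------------------------------------------------------
# Region annotation and HPO-style gene-trait links


def simulate_gene_annotation(config: SimConfig, n_genes: int = 30,
                             gene_length: int = 40_000) -> pd.DataFrame:
    """Evenly spaced gene spans tiling the region (gene, chrom, start, end)."""
    rng = config.rng(_STREAM_PROBES)
    starts = np.linspace(config.region_start + 50_000,
                         config.region_end - 50_000 - gene_length, n_genes).astype(np.int64)
    lengths = rng.integers(gene_length // 2, gene_length * 2, size=n_genes)
    return pd.DataFrame({
        "gene": [f"GENE{i:03d}" for i in range(n_genes)],
        "chrom": "22",
        "start": starts,
        "end": starts + lengths,
    })


def simulate_hpo_map(config: SimConfig, genes: pd.DataFrame, traits: pd.DataFrame,
                     links_per_gene: int = 6) -> pd.DataFrame:
    """Random static gene-to-trait links emulating a curated HPO mapping."""
    rng = config.rng(_STREAM_PROBES + 1)
    all_traits = list(traits["trait"])
    rows = []
    for gene in genes["gene"]:
        k = min(links_per_gene, len(all_traits))
        for t in rng.choice(all_traits, size=k, replace=False):
            rows.append({"gene": gene, "trait": t})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Summary-level pleiotropy experiment


def simulate_pleiotropy_experiment(config: SimConfig, mode: str = "mediation",
                                   n_pairs: int = 1, stream: int = 0,
                                   se_exposure: float = 0.05,
                                   se_observed: float = 0.15):
    """Simulate exposure-outcome pairs for the pleiotropy decomposition.

    ``mediation``: the CNV affects the outcome only through the exposure —
    the observed outcome effect is alpha x (CNV effect on exposure) plus
    estimation noise.  ``horizontal``: the CNV hits exposure and outcome
    independently.  The causal estimate is obtained by running IVW on
    simulated summary statistics (not read from the truth).  Returns a list
    of :class:`~cnvphewas.pleiotropy.PleiotropyPair`.

    The default standard errors are asymmetric — the observed CNV effect on
    the outcome rests on a handful of rare carriers and is several-fold
    noisier than the expected effect, whose two factors are each precisely
    estimated.  This mirrors the situation in real region-focused scans and
    matters for the CI-containment classification: with equal SEs the
    containment rule's theoretical true-positive rate under pure mediation
    sits near its nominal floor.
    """
    from .mr import harmonize, ivw
    from .pleiotropy import PleiotropyPair

    rng = config.rng(_STREAM_MR + 1000 + stream)
    pairs = []
    for i in range(n_pairs):
        alpha = float(rng.choice([-1, 1]) * rng.uniform(0.3, 0.8))
        beta_exp_true = float(rng.choice([-1, 1]) * rng.uniform(0.5, 1.5))
        se_exp = se_exposure
        se_obs = se_observed
        sub = SimConfig(
            n_samples=config.n_samples,
            mr_spec=MrSpec(genes=(f"X{i}",), n_ivs=config.mr_spec.n_ivs,
                           causal_effect=alpha,
                           n_exposure=config.mr_spec.n_exposure,
                           n_outcome=config.mr_spec.n_outcome),
            seed=int(rng.integers(2**31 - 1)),
        )
        eqtl, gwas, ld, _ = simulate_summary_stats(sub)
        est = ivw(harmonize(eqtl.drop(columns=["gene"]), gwas), min_ivs=1)
        beta_exp_hat = beta_exp_true + float(rng.normal(0.0, se_exp))
        if mode == "mediation":
            beta_obs = alpha * beta_exp_true + float(rng.normal(0.0, se_obs))
        elif mode == "horizontal":
            beta_obs = float(rng.choice([-1, 1]) * rng.uniform(0.5, 1.5)
                             + rng.normal(0.0, se_obs))
        else:
            raise ValueError("mode must be 'mediation' or 'horizontal'")
        pairs.append(PleiotropyPair(
            exposure=f"X{i}", outcome=f"Y{i}",
            beta_exposure=beta_exp_hat, se_exposure=se_exp,
            beta_ivw=est.beta, se_ivw=est.se,
            beta_observed=beta_obs, se_observed=se_obs,
        ))
    return pairs


# ---------------------------------------------------------------------------
# Dataset writer


def write_dataset(config: SimConfig, outdir) -> dict:
    """Simulate and write the full input bundle for the pipeline CLI.

    Emits calls.tsv, probes.bim, phenotypes.tsv, eqtl.tsv, gwas.tsv, ld.tsv,
    genes.tsv, hpo_map.tsv and truth.json under ``outdir``; returns the
    file-path map.
    """
    from .cnv_matrix import build_matrix, qc_filter_calls

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probes = simulate_probe_map(config)
    calls = simulate_cnv_calls(config)
    retained, _ = qc_filter_calls(calls[CALL_COLUMNS])
    matrix = build_matrix(retained, probes, sample_ids=sample_ids(config))
    pheno, truth_pheno = simulate_phenotypes(config, matrix)
    cont = [e.trait_name for e in config.planted_effects if e.trait_kind == "continuous"]
    outcome_name = cont[0] if cont else "outcome"
    eqtl, gwas, ld, truth_mr = simulate_summary_stats(config, outcome=outcome_name)
    truth_mr["outcome"] = outcome_name
    genes = simulate_gene_annotation(config)
    traits_meta = pd.DataFrame({
        "trait": [e.trait_name for e in config.planted_effects],
        "kind": [e.trait_kind for e in config.planted_effects],
    })
    hpo = simulate_hpo_map(config, genes, traits_meta) if len(traits_meta) else pd.DataFrame(columns=["gene", "trait"])

    paths = {
        "calls": outdir / "calls.tsv",
        "probes": outdir / "probes.bim",
        "phenotypes": outdir / "phenotypes.tsv",
        "eqtl": outdir / "eqtl.tsv",
        "gwas": outdir / "gwas.tsv",
        "ld": outdir / "ld.tsv",
        "genes": outdir / "genes.tsv",
        "hpo_map": outdir / "hpo_map.tsv",
        "truth": outdir / "truth.json",
    }
    genes.to_csv(paths["genes"], sep="\t", index=False)
    hpo.to_csv(paths["hpo_map"], sep="\t", index=False)
    calls[CALL_COLUMNS].to_csv(paths["calls"], sep="\t", index=False)
    probes.to_csv(paths["probes"], sep="\t", index=False, header=False)
    pheno.to_csv(paths["phenotypes"], sep="\t")
    eqtl.to_csv(paths["eqtl"], sep="\t", index=False)
    gwas.to_csv(paths["gwas"], sep="\t", index=False)
    ld.to_csv(paths["ld"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump({"phenotypes": truth_pheno, "mr": truth_mr,
                   "config": {"n_samples": config.n_samples, "seed": config.seed}},
                  fh, indent=1, default=str)
    return {k: str(v) for k, v in paths.items()}
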