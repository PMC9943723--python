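"""Table readers/writers, pipeline configuration and orchestration.

All canonical formats are header-carrying TSV (PennCNV-like call tables,
BIM-like probe maps, phenotype tables, GWAS/eQTL summary statistics, square
LD matrices, gene annotation and HPO gene-trait maps).  ``read_table``
validates each file against a named schema and reports the line and column
of the first violation.  ``run_pipeline`` chains matrix construction,
association scanning, multiplicity control, conditional analysis,
sensitivity testing, enrichment, MR and pleiotropy decomposition from a
single :class:`PipelineConfig`; identical config and seed give identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv_matrix, dosage, enrichment, mr, pleiotropy, scan, sensitivity
from .cnv_matrix import CnvMatrix

log = logging.getLogger("cnvphewas")

# column -> required kind ("num" coercible to float, "str" anything)
SCHEMAS = {
    "calls": {"sample_id": "str", "chrom": "str", "start": "num", "end": "num",
              "cn_class": "str", "qs": "num"},
    "probes": {"chrom": "str", "probe_id": "str", "cm": "num", "bp": "num"},
    "sumstats": {"snp_id": "str", "chrom": "str", "bp": "num",
                 "effect_allele": "str", "other_allele": "str", "eaf": "num",
                 "beta": "num", "se": "num", "pval": "num", "n": "num"},
    "genes": {"gene": "str", "chrom": "str", "start": "num", "end": "num"},
    "hpo_map": {"gene": "str", "trait": "str"},
}

_KEY_COLUMNS = {"probes": ["probe_id"], "sumstats": ["snp_id"], "genes": ["gene"]}


class TableFormatError(ValueError):
    """Structured parse error naming the file, line and column at fault."""


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV against a named schema.

    Numeric columns are strictly coerced; the first offending cell is
    reported with its 1-based line number (header = line 1).  Duplicate
    values in the schema's key column raise as well.  Gzip-compressed files
    are handled transparently by pandas.
    """
    spec = SCHEMAS[schema]
    header = 0 if schema != "probes" else None
    df = pd.read_csv(path, sep="\t", header=header, dtype=str,
                     keep_default_na=False, na_values=[""])
    if schema == "probes" and header is None:
        if df.shape[1] != len(spec):
            raise TableFormatError(f"{path}: probe map needs {len(spec)} columns, found {df.shape[1]}")
        df.columns = list(spec)
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    for col, kind in spec.items():
        if kind != "num":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise TableFormatError(
                f"{path}: non-numeric value {df[col][row]!r} in column "
                f"'{col}' at line {row + 2}"
            )
        df[col] = coerced
    for key in _KEY_COLUMNS.get(schema, []):
        dup = df[key][df[key].duplicated()]
        if len(dup):
            raise TableFormatError(f"{path}: duplicate key '{dup.iloc[0]}' in column '{key}'")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_ld(path) -> pd.DataFrame:
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    return ld


def write_matrix(matrix: CnvMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_matrix(path) -> CnvMatrix:
    return CnvMatrix.from_frame(pd.read_csv(path, sep="\t", index_col="probe_id"))


# ---------------------------------------------------------------------------
# Configuration


#: Covariate columns recognised in a phenotype table.
_COVARIATE_PREFIXES = ("age", "sex", "batch", "pc")


@dataclass
class PipelineConfig:
    """File paths plus every tunable threshold, at its published default."""

    # inputs
    calls: str = "calls.tsv"
    probes: str = "probes.bim"
    phenotypes: str = "phenotypes.tsv"
    eqtl: str | None = None
    gwas: str | None = None
    ld: str | None = None
    genes: str | None = None
    hpo_map: str | None = None
    gwas_outcome: str = "outcome"  # trait the GWAS summary stats describe
    out_dir: str = "results"
    # trait lists (inferred from the phenotype table when empty)
    continuous_traits: list = field(default_factory=list)
    binary_traits: list = field(default_factory=list)
    # thresholds
    qs_min: float = 0.5
    max_missing: float = 0.05
    r2_min: float = 0.999
    min_partners: int = 10
    var_fraction: float = 0.995
    alpha_base: float = 0.05
    fisher_p: float = 0.005
    trend_p: float = 0.0005
    residual_p: float = 0.005
    min_ivs: int = 5
    steiger_alpha: float = 5e-3
    clump_r2: float = 0.001
    twmr_iv_r2: float = 0.01
    maf_min: float = 0.01
    max_af_diff: float = 0.05
    p0: float = 0.05
    gene_window: int = 10_000
    models: tuple = dosage.MODELS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["models"] = list(d["models"])
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def split_trait_columns(pheno: pd.DataFrame, config: PipelineConfig):
    """Partition phenotype columns into covariates / continuous / binary.

    Covariates are recognised by name prefix (age, sex, batch, pc); among
    the remaining columns, those listed in the config are used as given,
    otherwise 0/1-valued columns are classed binary and the rest continuous.
    """
    cov_cols = [c for c in pheno.columns if c.lower().startswith(_COVARIATE_PREFIXES)]
    trait_cols = [c for c in pheno.columns if c not in cov_cols]
    if config.continuous_traits or config.binary_traits:
        cont = [c for c in trait_cols if c in config.continuous_traits]
        binr = [c for c in trait_cols if c in config.binary_traits]
    else:
        binr = [c for c in trait_cols
                if set(pheno[c].dropna().unique()) <= {0, 1, 0.0, 1.0}]
        cont = [c for c in trait_cols if c not in binr]
    return cov_cols, cont, binr


# ---------------------------------------------------------------------------
# Orchestration


def sensitivity_table(assoc: pd.DataFrame, scan_matrix: CnvMatrix,
                      resid_df: pd.DataFrame, pheno: pd.DataFrame,
                      covariates: pd.DataFrame, selected_covs: dict) -> pd.DataFrame:
    """Confirmatory test p values for each association row.

    Continuous traits (columns of ``resid_df``) get a carrier-vs-neutral
    Wilcoxon; binary traits get Fisher/trend (by model) and the
    residual-regression confirmation.
    """
    rows = []
    for rec in assoc.itertuples(index=False):
        i = scan_matrix.probe_ids.index(rec.probe_id)
        states = scan_matrix.states[i]
        dose = dosage.encode(states, rec.model)
        row = {"probe_id": rec.probe_id, "trait": rec.trait, "model": rec.model,
               "wilcoxon_p": np.nan, "fisher_p": np.nan, "trend_p": np.nan,
               "residual_p": np.nan}
        if rec.trait in resid_df.columns:
            y = resid_df[rec.trait].to_numpy()
            carriers = y[(dose != 0) & ~np.isnan(dose)]
            neutral = y[dose == 0]
            if carriers.size and neutral.size:
                row["wilcoxon_p"] = sensitivity.wilcoxon_rank_sum(carriers, neutral)
        else:
            y = pheno[rec.trait].to_numpy(dtype=float)
            if rec.model == "mirror":
                row["trend_p"] = sensitivity.cochran_armitage_trend(
                    sensitivity.mirror_table(states, y))
            else:
                row["fisher_p"] = sensitivity.fisher_exact_2x2(
                    sensitivity.carrier_table(dose, y))
            row["residual_p"] = sensitivity.residual_confirmation(
                y, covariates[selected_covs.get(rec.trait, [])], dose)
        rows.append(row)
    return pd.DataFrame(rows, columns=["probe_id", "trait", "model", "wilcoxon_p",
                                       "fisher_p", "trend_p", "residual_p"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full scan from files to result bundle.

    Stages: call QC -> matrix -> probe selection -> per-model scans ->
    effective-test multiplicity -> stepwise conditional analysis ->
    sensitivity confirmation -> (optional) HPO enrichment -> (optional)
    TWMR -> (optional) TWMR/scan concordance.  Optional stages run only
    when their input files are configured.  All outputs are written as
    TSV/JSON under ``config.out_dir``; the returned dict holds every
    in-memory result.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": asdict(config)}

    calls = read_table(config.calls, "calls")
    probes = read_table(config.probes, "probes")
    pheno = read_phenotypes(config.phenotypes)
    cov_cols, cont_traits, bin_traits = split_trait_columns(pheno, config)
    log.info("inputs: %d calls, %d probes, %d samples, %d continuous + %d binary traits",
             len(calls), len(probes), len(pheno), len(cont_traits), len(bin_traits))

    # --- matrix construction and probe selection
    retained_calls, excluded = cnv_matrix.qc_filter_calls(calls, qs_min=config.qs_min)
    keep = ~pheno.index.isin(excluded)
    pheno = pheno[keep]
    matrix = cnv_matrix.build_matrix(retained_calls, probes, sample_ids=list(pheno.index))
    keep_probes = cnv_matrix.filter_missingness(matrix, config.max_missing)
    matrix = matrix.subset_probes(keep_probes)
    pruned = cnv_matrix.prune_probes(matrix, config.r2_min, config.min_partners)
    scan_matrix = matrix.subset_probes(pruned) if pruned else matrix
    log.info("QC: %d calls kept, %d samples excluded; %d/%d probes retained after pruning",
             len(retained_calls), len(excluded), scan_matrix.n_probes, matrix.n_probes)
    bundle["matrix"] = scan_matrix
    bundle["probe_summary"] = cnv_matrix.probe_summary(
        matrix, config.max_missing, config.r2_min, config.min_partners)
    bundle["probe_summary"].to_csv(out / "probe_summary.tsv", sep="\t", index=False)

    # --- trait preprocessing
    covariates = pheno[cov_cols]
    resid = {}
    for t in cont_traits:
        resid[t] = scan.residualize_continuous(
            scan.inverse_normal_transform(pheno[t]), covariates)
    resid_df = pd.DataFrame(resid, index=pheno.index)
    selected_covs = {}
    for t in bin_traits:
        selected_covs[t], _ = scan.select_covariates_binary(
            pheno[t], covariates, alpha=config.alpha_base)

    # --- association scans
    results = []
    for model in config.models:
        if cont_traits:
            res = scan.linear_scan(scan_matrix, model, resid_df)
            res["trait_kind"] = "continuous"
            results.append(res)
        for t in bin_traits:
            res = scan.logistic_scan(scan_matrix, model, pheno[t],
                                     covariates[selected_covs[t]])
            res["trait_kind"] = "binary"
            results.append(res)
    assoc = pd.concat(results, ignore_index=True) if results else pd.DataFrame(columns=scan.RESULT_COLUMNS)
    for model in config.models:
        write_table(assoc[assoc["model"] == model], out / f"scan_{model.replace('-', '_')}.tsv")

    # --- multiplicity
    neff_probes = scan.effective_tests(cnv_matrix.probe_correlation(scan_matrix),
                                       config.var_fraction)
    neff_cont = (scan.effective_tests(scan.trait_correlation(resid_df), config.var_fraction)
                 if len(cont_traits) > 1 else len(cont_traits))
    neff_bin = (scan.effective_tests(scan.trait_correlation(pheno[bin_traits]), config.var_fraction)
                if len(bin_traits) > 1 else len(bin_traits))
    mult = scan.significance_threshold(neff_probes, neff_cont, neff_bin, config.alpha_base)
    bundle["multiplicity"] = mult
    (out / "multiplicity.json").write_text(json.dumps(asdict(mult), indent=1))
    log.info("multiplicity: %d effective tests, alpha = %.3g", mult.neff_total, mult.alpha)

    ok = assoc["skip_reason"].isna() & assoc["p"].notna()
    sig = assoc[ok & (assoc["p"] <= mult.alpha)].copy()
    bundle["associations"] = assoc
    bundle["significant"] = sig
    write_table(sig, out / "significant.tsv")

    # --- conditional analysis per significant (trait, model)
    leads_rows = []
    for (trait, model), grp in sig.groupby(["trait", "model"], sort=False):
        if trait not in resid_df.columns:
            continue  # stepwise conditioning operates on residualised traits
        leads = scan.conditional_scan(scan_matrix, model, resid_df[trait], mult.alpha)
        leads["trait"] = trait
        leads["model"] = model
        leads_rows.append(leads)
    leads_df = (pd.concat(leads_rows, ignore_index=True) if leads_rows
                else pd.DataFrame(columns=["step", "probe_id", "bp", "effect", "se", "p", "trait", "model"]))
    bundle["leads"] = leads_df
    write_table(leads_df, out / "leads.tsv")

    # --- sensitivity confirmation of significant hits
    sens_df = sensitivity_table(sig, scan_matrix, resid_df, pheno, covariates, selected_covs)
    verdicts = (sensitivity.apply_retention_rules(sig, sens_df) if len(sig)
                else pd.DataFrame())
    bundle["sensitivity"] = verdicts
    if len(verdicts):
        write_table(verdicts, out / "sensitivity.tsv")

    # --- optional HPO enrichment
    if config.genes and config.hpo_map:
        genes = read_table(config.genes, "genes")
        hpo = read_table(config.hpo_map, "hpo_map")
        traits_meta = pd.DataFrame(
            {"trait": cont_traits + bin_traits,
             "kind": ["continuous"] * len(cont_traits) + ["binary"] * len(bin_traits)})
        enr = {}
        for model in config.models:
            for kind in ("continuous", "binary"):
                res = enrichment.enrichment_analysis(
                    assoc[ok], scan_matrix, hpo, traits_meta, genes,
                    model, kind, p0=config.p0, window=config.gene_window)
                enr[f"{model}|{kind}"] = res
        bundle["enrichment"] = enr
        summary = {k: {kk: v[kk] for kk in ("n_genes", "n_significant", "fold", "binomial_p")}
                   for k, v in enr.items()}
        (out / "enrichment.json").write_text(json.dumps(summary, indent=1))

    # --- optional TWMR + concordance
    if config.eqtl and config.gwas and config.ld:
        eqtl = read_table(config.eqtl, "sumstats")
        eqtl["gene"] = pd.read_csv(config.eqtl, sep="\t", dtype=str)["gene"]
        gwas = read_table(config.gwas, "sumstats")
        ld = read_ld(config.ld)
        ests = []
        for gene, sub in eqtl.groupby("gene", sort=False):
            est = mr.twmr_pipeline(
                gene, sub.drop(columns=["gene"]), gwas, ld,
                outcome=config.gwas_outcome,
                iv_r2=config.twmr_iv_r2, maf_min=config.maf_min,
                max_af_diff=config.max_af_diff, steiger_alpha=config.steiger_alpha,
                min_ivs=config.min_ivs)
            ests.append(est)
        twmr_df = pd.DataFrame([asdict(e) for e in ests])
        tested = twmr_df["beta"].notna().sum()
        twmr_df["significant"] = (twmr_df["p"] <= mr.twmr_significance_threshold(max(int(tested), 1))
                                  ) & twmr_df["beta"].notna()
        bundle["twmr"] = twmr_df
        write_table(twmr_df, out / "twmr.tsv")
        if config.genes is not None:
            genes = read_table(config.genes, "genes")
            mirror_scan = assoc[(assoc["model"] == "mirror") & ok]
            conc = pleiotropy.twmr_scan_concordance(
                twmr_df.rename(columns={"exposure": "gene"}),
                mirror_scan, genes, window=config.gene_window)
            bundle["concordance"] = conc
            (out / "concordance.json").write_text(json.dumps(conc["summary"], indent=1))

    log.info("pipeline complete: %d significant associations", len(sig))
    return bundle
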