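# cnvphewas

Region-focused copy-number-variant (CNV) phenome-wide association analysis,
from PennCNV-style call tables to causal follow-up.

Recurrent CNVs — such as the low-copy-repeat (LCR) mediated deletions and
duplications of chromosome 22q11.2 — are individually rare but collectively
shape many human traits. Because their breakpoints vary between carriers,
this package scans at the *probe* level: calls are converted into a
probe-by-sample copy-number state matrix (deletion = −1, copy-neutral = 0,
duplication = +1) and every probe is tested against every trait under four
dosage models:

| model            | dosage of (del, neutral, dup) | mechanism tested |
|------------------|-------------------------------|------------------|
| deletion-only    | (1, 0, ·)                     | deletions matter, duplications disregarded |
| duplication-only | (·, 0, 1)                     | duplications matter, deletions disregarded |
| mirror           | (−1, 0, +1)                   | each extra copy shifts the trait one way |
| U-shape          | (1, 0, 1)                     | any carrier deviates in the same direction |

Continuous traits are rank-based inverse-normal transformed and
residualised on covariates (age, age², sex, batch, PCs), then regressed on
the dosage; binary traits use logistic regression with trait-specific
covariate selection and a Firth-penalised fallback for separation-prone
rare-carrier fits. Multiplicity is controlled through the effective number
of independent tests, `N_eff = N_eff_probes × (N_eff_continuous +
N_eff_binary)`, where each factor is the number of top eigenvalues of the
corresponding correlation matrix needed to capture 99.5% of its trace, and
the scan threshold is `α = 0.05 / N_eff`. Significant hits pass stepwise
conditional analysis, exact confirmatory tests (Wilcoxon rank-sum, Fisher's
exact, Cochran-Armitage trend, inverse-normal residual regression), and
HPO-guided gene-level enrichment. Transcriptome-wide Mendelian
randomization (fixed-effect IVW on ≥5 independent eQTL instruments, after
harmonization, LD clumping and Steiger directionality filtering) links gene
expression to the associated traits, and a pleiotropy decomposition
compares the CNV effect on an outcome expected under mediation,
`β_expected = β_exposure × β_IVW`, with the effect observed directly.

Because the cohort data such analyses run on are access-restricted, the
package ships a first-class synthetic-data generator
(`cnvphewas.simulate`) that emulates every input — LCR-anchored CNV calls
with quality scores, phenotypes with effects planted under any dosage
model, and MR summary statistics with planted causal effects, pleiotropic,
palindromic and reverse-causal instruments — so the whole pipeline is
testable end to end.

## Worked example

Simulate a 10,000-sample cohort with a mirror-model effect (−0.8 SD per
copy) planted on a low-frequency CNV region, then recover it:

```python
import pandas as pd
from cnvphewas import (SimConfig, PlantedEffect, simulate_cnv_calls,
                       qc_filter_calls, build_matrix, linear_scan,
                       inverse_normal_transform, residualize_continuous)
from cnvphewas.simulate import simulate_probe_map, simulate_phenotypes, sample_ids

cfg = SimConfig(
    n_samples=10_000, n_probes=200, seed=1,
    planted_effects=[
        PlantedEffect("mpv", "continuous", "mirror", -0.8, (18_700_000, 20_400_000)),
        PlantedEffect("null_trait", "continuous", "mirror", 0.0, (18_700_000, 21_800_000)),
    ])
calls = simulate_cnv_calls(cfg)
kept, _ = qc_filter_calls(calls[["sample_id", "chrom", "start", "end", "cn_class", "qs"]])
matrix = build_matrix(kept, simulate_probe_map(cfg), sample_ids=sample_ids(cfg))
pheno, truth = simulate_phenotypes(cfg, matrix)
cov = [c for c in pheno.columns if c.lower().startswith(("age", "sex", "batch", "pc"))]
y = residualize_continuous(inverse_normal_transform(pheno["mpv"]), pheno[cov])
res = linear_scan(matrix, "mirror", pd.Series(y, index=pheno.index, name="mpv"))
print(res.loc[res["p"].idxmin()])
```

This prints (among other columns):

```
calls: 438 simulated, 410 pass QC
lead probe probe0101 at chr22:20294724
beta = -0.665 [-0.776, -0.555], p = 7.93e-32
carriers at lead: 86 del / 144 dup / 9770 neutral
```

The planted per-copy effect of −0.8 trait SD is recovered as −0.67 on the
inverse-normal scale (the transform plus covariate noise attenuates the raw
coefficient; the estimate is within sampling error of the attenuated
truth), at a p value far beyond any multiplicity threshold, driven by 230
carriers among 10,000 samples.

The same analysis runs from the shell:

```bash
cnv-phewas simulate --out data/ --seed 1 --n-samples 10000
cnv-phewas run-all --print-config        # dump every threshold and default
cnv-phewas build-matrix --calls data/calls.tsv --probes data/probes.bim --out m.tsv
```

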