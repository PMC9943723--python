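# Methods

## The probe-level scan

CNV calls (one genomic span per carrier, with a quality score QS in [−1, 1]
whose magnitude approximates the probability of a true positive) are first
quality-controlled: calls with |QS| < 0.5 are dropped, and all calls are
removed from samples on genotyping plates with a mean CNV count per sample
above 100, from samples with more than 200 calls, or from samples
harbouring any single call longer than 10 Mb. Retained calls are rasterised
onto the probe map: probe *p* takes state −1/+1 for sample *s* iff a
retained deletion/duplication call satisfies `start ≤ bp(p) ≤ end`
(coordinates 1-based inclusive, the PennCNV convention), 0 otherwise. When
the same sample carries both a deletion and a duplication over one probe
the state is set missing — the conservative choice for an ambiguity the
calling pipeline cannot resolve.

Probes with more than 5% missing entries are excluded; the remainder are
pruned to proxy probes whose copy-number states are highly correlated
(r² ≥ 0.999, Pearson on the raw −1/0/+1 states with pairwise-complete
observations) with at least ten other probes. Raw states are the only
model-neutral encoding for this correlation; zero-variance probes are
assigned correlation 0 so they can never serve as pruning partners.

Each probe's states are encoded into four dosages (deletion-only,
duplication-only, mirror, U-shape; see README table). Signs are chosen so a
positive coefficient always means a higher trait value in the carrier /
per-additional-copy direction. Two algebraic identities follow and are used
as tests: on deletion-free samples the duplication-only, mirror and U-shape
dosages are the same vector, so all three scans return identical estimates;
on duplication-free samples deletion-only = −mirror = U-shape.

Continuous traits are inverse-normal transformed (Blom offset:
`Φ⁻¹((r − 3/8)/(n + 1/4))`, average ranks for ties — the common GWAS
default), then residualised on covariates by OLS; residuals are not
re-transformed. The scan itself is simple linear regression of the residual
trait on the dosage with a Wald t test, computed in closed form and
vectorised across traits. Binary traits select covariates by univariable
logistic screening (Wald p ≤ 0.05 per candidate; a candidate showing
separation is selected and flagged — separation implies strong marginal
association), then fit outcome ~ dosage + selected covariates by
Newton-Raphson logistic regression. When the fit does not converge, or a
carrier-by-outcome cell is empty, the fit falls back to Firth's
Jeffreys-prior penalised likelihood and the record is flagged; with 0–3
affected carriers this is routine, and the penalty keeps estimates and CIs
finite. With no covariates the logistic fit collapses the data to the
(dosage level × outcome) contingency table and fits the grouped likelihood,
which is exact and makes thousand-trait calibration runs cheap.

Probes whose dosage is degenerate after missingness (a single class, or
fewer than three usable samples) yield skipped-record markers rather than
exceptions, so a scan over many probes never aborts on an edge case.

## Multiplicity

The effective number of independent tests among correlated variables is
the smallest m such that the m largest eigenvalues of their correlation
matrix sum to at least 99.5% of its trace. This is computed separately for
the pruned probes (on the probe-state correlation matrix), the continuous
traits (Pearson correlation of the transformed values) and the binary
traits (Pearson on 0/1), and combined as
`N_eff = N_eff_probes × (N_eff_continuous + N_eff_binary)`, giving the
scan-wide threshold `α = 0.05 / N_eff`. With the published component counts
(6, 16, 113) this yields 774 tests and α = 6.5 × 10⁻⁵. Two boundary facts
worth noting: k perfectly correlated variables give m = 1; k uncorrelated
variables give m = k for k ≤ 199 but m = 199 at exactly k = 200, where
0.995·k is an integer and the ≥ comparison is met one eigenvalue early.

## Conditional and sensitivity analyses

Independent signals per (trait, model) are counted by stepwise conditional
analysis: the minimum-p probe with p ≤ α becomes a lead, its raw
copy-number state (the mirror encoding — CNV status, not the scan model's
encoding) is regressed out of the residual trait, and the scan repeats
until no probe passes. Because a U-shape signal is not exhausted by
conditioning on the mirror state, the loop also stops when the same probe
is re-elected lead (no progress); a `condition="carrier"` mode that removes
separate deletion- and duplication-carrier indicators is available.

Significant binary associations are retained only when confirmed by at
least one of two routes: (1) Fisher's exact test p ≤ 0.005 (carrier ×
case/control table, per the model's carrier definition) for the
deletion-only, duplication-only and U-shape models, or the Cochran-Armitage
trend test p ≤ 0.0005 (case/control over the ordered CN classes scored
−1/0/+1) for the mirror model; (2) linear regression p ≤ 0.005 of the
inverse-normal-transformed deviance residuals of the covariate-only
logistic fit on the dosage. Continuous hits are annotated with a Wilcoxon
rank-sum comparison of carriers vs copy-neutral samples but never dropped
automatically. Retention is monotone: lowering a confirmatory p value can
only preserve or create confirmation.

Exact p values: the Wilcoxon rank-sum test enumerates all rank splits
(midranks for ties) whenever `C(n1+n2, n1) ≤ 2×10⁵`; tie-free larger
samples use the exact Mann-Whitney distribution up to `n1·n2 ≤ 4×10⁴`
(beyond which the shift algorithm costs tens of seconds while the
tie/continuity-corrected normal approximation matches it to several
decimals); everything else is asymptotic. Fisher's exact test uses the
probability-mass two-sided rule; a zero margin returns p = 1 by convention.
The Cochran-Armitage statistic is the classic score test
`U²/Var(U)` with `U = Σ sᵢ(rᵢ − nᵢ·p̄)` on 1 df.

## Enrichment

For each gene (span ± 10 kb, inclusive), traits split into those linked to
the gene by the static HPO gene→trait map and those linked only to other
region genes. Genes need at least four continuous and ten binary traits in
each group to be compared. For every probe in the window, a one-sided
Wilcoxon rank-sum test asks whether the linked traits' association p values
are smaller (this direction follows the analysis's results convention; the
alternative reading would reverse it). The gene is significant when its
smallest probe p value reaches the gene-specific threshold 0.05/N_eff(gene)
(effective tests of the window's probe correlation matrix), and the number
of significant genes is summarised as a fold enrichment
`n_sig/(n_genes·p0)` with an upper-tail exact binomial p value. The null
probability p0 defaults to 0.05 — the per-gene error rate after
gene-specific correction — and reproduces the published 15-fold for 6
significant genes of 8.

## Mendelian randomization

Exposure (eQTL) and outcome (GWAS) summary statistics are harmonized to
the exposure's effect allele: swapped-allele records get their beta negated
and allele frequency complemented; palindromic SNPs (A/T, C/G) and SNPs
with a post-alignment allele-frequency difference above 0.05 are removed.
Instruments are pruned by greedy p-value-ordered LD clumping after a
MAF > 0.01 filter (r² < 0.01 for transcript instruments, r² = 0.001 for
trait-trait MR — both parameters). Steiger filtering removes instruments
that explain significantly more outcome than exposure variance: variance
explained is `2·eaf·(1−eaf)·β²` per side (standardized effects), the
implied correlations are compared on the Fisher z scale with the two sample
sizes, and an instrument is dropped when r²_out > r²_exp with one-sided
p < 5 × 10⁻³. Instruments with missing allele frequency are kept and
flagged untested.

The causal estimate is fixed-effect inverse-variance weighting,
`α̂ = Σwᵢβ_out,ᵢβ_exp,ᵢ / Σwᵢβ_exp,ᵢ²` with `wᵢ = 1/se_out,ᵢ²` and
`SE = (Σwᵢβ_exp,ᵢ²)^{−1/2}`; estimates from fewer than five surviving
instruments are withheld. Multivariable MR regresses the outcome betas on
all exposure beta columns jointly (weighted least squares, no intercept),
and equals IVW exactly in the single-exposure case. Transcript-level
significance uses 0.05 over the number of transcripts tested (0.003 for
17); cross-trait MR uses 0.05 over the square of the trait count (all
ordered exposure-outcome combinations: 289 for 17 traits, threshold
0.0002).

The fixed-effect IVW standard error conditions on the exposure effects
being known. The neglected exposure-side sampling noise inflates the true
dispersion of α̂ by roughly a factor `1 + α²·n_out/n_exp` in variance, so
CI coverage is nominal only where `α²·n_out/n_exp ≪ 1`. At the scale of
real transcript-to-trait effects (|α| ≈ 0.05 trait SD per expression SD,
n_out/n_exp ≈ 10) the inflation is ~2.5% and coverage is nominal; at
artificially large planted effects (α ≈ 0.3) the same estimator genuinely
undercovers — a property of fixed-effect IVW, not an implementation issue.
The generator's default causal effect sits at the realistic scale for this
reason. A multi-transcript LD-aware transcriptome-wide estimator is out of
scope; the core here is IVW on independent instruments.

## Pleiotropy decomposition

For an exposure-outcome trait pair, the CNV effect on the outcome expected
under pure mediation is `β_expected = β_exposure × β_IVW` (best mirror
probe effect times the IVW causal estimate), with SE by first-order error
propagation assuming independent inputs. A pair is vertical-consistent
when the expected and observed effects agree in sign and either point
estimate lies within the other's 95% CI; the sign-only mode drops the
containment condition. The CI rule's true-positive rate under pure
mediation is itself bounded: with SEs se₁ (expected) and se₂ (observed) it
is approximately `P(|Z| < 1.96·max(se₁,se₂)/√(se₁²+se₂²))`, i.e. ~88% when
the SEs are equal and ~94% when one dominates threefold. In region-focused
scans the observed CNV-outcome effect rests on a handful of rare carriers
and is several-fold noisier than the product of two precisely estimated
factors, which is the regime the synthetic experiment reproduces
(default se_exposure = 0.05, se_observed = 0.15).

Directional concordance between transcript-level MR and the mirror scan
pairs each nominally significant (p < 0.05) transcript estimate with the
minimum-p nominally significant mirror probe in the gene ± 10 kb (ties
broken by smaller position) and summarises agreement with a zero-intercept
weighted least-squares slope `Σwxy/Σwx²` (weights 1/se² of the scan
effect), with a Wald t test on n−1 df.

## The synthetic-data generator

The generator emulates the inputs of a biobank-scale region-focused scan:

* **CNV calls.** Carrier counts per LCR category and type are binomial at
  configured frequencies; default frequencies are the published
  population rates inflated tenfold so planted effects are recoverable at
  simulated cohort sizes (`population_frequencies()` restores the population
  scale: A-B dup 0.01%/del 0.002%, A-D 0.06%/0.001%, B-D 0.002%/0,
  C-D 0.04%/0.008%, atypical 0.16%/0.16%). Breakpoints sit at the flanking
  LCR boundaries with ±20 kb uniform jitter (breakpoint variability is
  real but unquantified; 20 kb is a probe-spacing-scale choice); atypical
  calls get uniform spans of 80 kb–2 Mb. Each sample carries at most one
  call by default (they are rare; a multi-call flag exists). |QS| follows
  Beta(5, 1) — right-skewed toward confident calls — signed negative for
  deletions and positive for duplications (the sign convention is not
  standardised; it is configurable), with a configurable 5% of calls
  drawn below the 0.5 retention threshold to exercise the QC filter.
* **Phenotypes.** Covariates: age ~ U(40, 69), sex ~ Bernoulli(½), four
  batches, 10 standard-normal PCs (a cohort analysis would use 40; ten
  suffice to exercise residualisation). Continuous traits are a fixed
  seed-determined covariate linear predictor plus effect_size × encoded
  dosage plus standard normal noise; binary traits are Bernoulli through a
  logistic link at the configured prevalence (the downstream scan is
  logistic, so the generative link matches), shifted by effect_size
  log-odds times the dosage. Zero effect size gives exact nulls.
* **Summary statistics.** Per gene, n_ivs independent instruments with
  true exposure effects ±U(0.2, 0.5) (lead cis-eQTLs are strong), standard
  errors `1/√(2·eaf·(1−eaf)·n)` for the stated sample sizes (defaults
  30,000 exposure / 300,000 outcome), and outcome effects α × exposure
  effect plus optional horizontal pleiotropy noise. Configured fractions of
  palindromic allele pairs, allele-frequency mismatches, swapped-allele
  outcome records and reverse-causal instruments (tiny exposure effect,
  large outcome effect) are injected and recorded in the returned ground
  truth. The LD matrix is the identity — instruments are simulated
  independent; clumping is tested against explicitly constructed LD blocks.

What the generator does **not** emulate: raw intensity data (LRR/BAF),
genome-wide background CNVs, population stratification and relatedness,
linkage between instruments and phenotype-cohort overlap. Passing tests
therefore demonstrate the statistical machinery is correct under the
model's own assumptions, not robustness to confounding a real cohort would
add.

All randomness derives from a single integer seed via per-purpose
substreams; identical configuration reproduces every table byte for byte.

## Numerical choices and problem sizes

Wald CIs at 95% throughout; p values floored at 5×10⁻³²⁴ so exact fits
never report p = 0. IRLS converges at step max-norm < 10⁻⁹ (Firth 10⁻⁸ with
step-halving); coefficients beyond ±30 on the logit scale are treated as
separation. Eigenvalues are clipped at zero before cumulation. Matrix
correlation uses BLAS on complete data and pandas pairwise-complete
correlation only when missing entries exist.

Test and acceptance runs use scaled-down problem sizes chosen to keep the
statistical properties measurable: cohorts of 5,000–20,000 samples with
carrier frequencies ≥ 0.5%, 20–200 probes, 400–1,000 null traits for
calibration, 200–500 seeds for coverage, and 300 pairs per pleiotropy
experiment. These sizes give binomial/Monte-Carlo standard errors several
times smaller than the property margins they are checked against.
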