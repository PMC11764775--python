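# Methods

## Scope and model

`metspgs` implements a single-cohort, candidate-panel polygenic-score
study for a binary outcome (metabolic syndrome). The statistical chain
is: per-variant additive-model association → multiple-testing control →
risk-allele-oriented score construction → nested logistic risk models
compared by discrimination and reclassification. All evaluation is
in-sample (models fitted and assessed on the same cohort), matching the
single-cohort prognostic design it emulates; a cross-validation split is
deliberately out of scope for the default workflow.

## Synthetic cohorts

Two generative modes share one `numpy.random.Generator` stream, so a
fixed seed makes every output byte-identical.

**Retrospective (case-control) mode** mirrors the sampling design of a
case-control study: group sizes are fixed (defaults 279 cases, 397
controls), and each locus is drawn independently per group under
Hardy-Weinberg equilibrium at that group's effect-allele frequency,
P(g = k) = C(2, k)·pᵏ(1−p)²⁻ᵏ. The packaged 18-locus panel supplies
group-specific frequencies (derived from minor-allele frequencies via
EAF = MAF when the effect allele is the minor allele, else 1 − MAF) and
published per-allele odds ratios used as score weights.

**Prospective (population) mode** draws genotypes at the population
frequency and assigns status from the additive logistic liability
logit P(case) = α + Σ log(ORᵢ)·gᵢ, with α solved by bracketed root
finding so the population case fraction hits the target prevalence
(default 0.3, a plausible adult MetS prevalence; the emulated study
reports none). The population pool (20× the cohort by default) is then
sub-sampled to the requested group sizes. This mode exists to verify,
not to reproduce: the retrospective fit must recover the generating OR
with nominal CI coverage, and does.

**Covariates.** Age ~ Normal(55, 10) truncated to [18, 90] and
sex ~ Bernoulli(0.5), both independent of status. The study being
emulated reports no cohort age/sex summaries, so these are explicit
stand-ins chosen to make the covariates non-informative — which
isolates the genetic contribution to AUC and matches the finding that
age and sex add little. Consequences: the age+sex reference model is a
null model (AUC ≈ 50%), and the covariate-adjusted AUC is driven
entirely by the score.

**Linkage disequilibrium** is injected on demand via a Gaussian copula:
each of the target variant's two allele draws is thresholded from a
latent normal correlated with a latent consistent with the observed
allele of the partner variant (truncated-normal reconstruction), with
the latent correlation solved from the bivariate-normal orthant
probability so the allele-level Pearson correlation hits √r². Per-group
allele frequencies are preserved. At unequal allele frequencies the
maximal attainable correlation is below 1 (Fréchet bound); the
requested value is then clipped with a warning, best effort. r² = 1
short-circuits to column duplication, r² = 0 to an independent redraw.

**Quantitative phenotypes** (endophenotype fixtures) are
trait = intercept + β·g + β_age·age + β_sex·sex + Normal(0, σ) noise,
giving linear-regression round-trip checks a known truth.

**What the generator does not emulate:** population structure and
cryptic relatedness, genotyping batch effects, haplotype-scale LD
(injection is pairwise only), covariate-outcome confounding, and any
real correlation between age/sex and MetS. Passing tests therefore
show the statistical machinery is correct under the stated sampling
model — not that the published cohort's data-specific estimates (its
adjusted ORs, endophenotype betas, or group score means) are
recoverable; those depend on unpublished individual-level data.

## Association stage

Per-variant logistic (or, for quantitative traits, OLS) regression under
the additive model with age and sex as default covariates, fitted by
IRLS maximum likelihood (statsmodels GLM; deviance tolerance 1e-8, max
50 iterations). Wald z = β/se, two-sided normal p, OR CI
exp(β ± 1.96·se). Missing dosages are excluded listwise per variant.
Non-convergence and separation (|β| > 15 on the dosage term, or a
perfect-separation warning from the optimizer) return a flagged result
carrying an error code and NaN statistics — never silent numbers.
Monomorphic dosage raises immediately in a single fit and is flagged in
a panel scan. Protective fits are re-fit under the complementary coding
g → 2 − g, which exactly negates β and inverts the OR while leaving se
and p unchanged (verified to floating tolerance).

The Hardy-Weinberg exact test evaluates the conditional distribution of
the heterozygote count given allele totals,
P(h) = 2ʰ N! n_A! n_B! / (n_homA! h! n_homB! (2N)!), summing the
probabilities of all configurations no more probable than the observed
one (log-gamma arithmetic; ties included with a 1e-12 log-space
tolerance). Monomorphic counts give p = 1. Computed in controls by
default — the standard genotyping-QC convention — and configurable to
cases or the combined sample.

Benjamini-Hochberg is implemented with an explicit family size
`m_total ≥ n` so that the significant subset of a larger genotyped panel
can be adjusted against the full panel size; this is exactly the
situation of a published table printing 18 significant rows from a
40-variant panel, and is valid when the unprinted p-values all rank
above the largest printed one. The adjusted values are the usual
min-over-tail of m·p₍ⱼ₎/j, clipped at 1, ties sharing their tail
minimum.

## Scores

Default weights are the raw age/sex-adjusted ORs (≥ 1 after flipping),
because that is the weighting the emulated study states; log-OR mode is
provided as the field-standard alternative and used nowhere in the
reproduction workflow. LD pruning visits candidates in ascending
association p (ties by variant id) and drops any candidate whose dosage
r² with an already-kept same-chromosome variant reaches the threshold
(default 0.5 — the study states none — configurable). Missing dosages
default to expected-dosage imputation (2 × overall risk-allele
frequency) so every sample receives a score, which downstream
reclassification requires; per-sample rescaling by observed loci is the
alternative. `n_loci_used` counts observed loci, with 0 flagging a
fully missing sample. No standardization by default; scores are on the
natural Σw·g scale.

## Risk models and their comparison

Logistic models on any subset of {weighted score, unweighted score,
age, sex, phenotypes}; in-sample predicted probabilities. AUC is the
midrank Mann-Whitney statistic (exactly the exhaustive
concordant-pair count with ties at half weight), with variance by the
DeLong structural-components estimator and a normal 95% CI clipped to
[0, 1]. Continuous (category-free) NRI counts only the sign of the
per-sample prediction change between models, so it is invariant to any
common strictly monotone rescaling; total = event + non-event
components identically. Inference: bootstrap stratified by
case/control status (default B = 1000, percentile CI, seedable), with
the p-value from the normal approximation z = NRI/SE — standard
practice where the original study's method is unstated. Identical
predictions short-circuit to NRI 0, p 1. Binned NRI with user
thresholds is intentionally not the default: the emulated study reports
continuous values.

One documented discrepancy: the study's reclassification table calls
its NRI values percentages, yet its total of 1.03 sits on the continuous
NRI scale (bounded by ±2). This package reports continuous NRI on its
natural scale throughout.

## Numerical and design choices

* Wald tests and CIs everywhere (the study's symmetric OR CIs are
  consistent with Wald); likelihood-ratio alternatives are not exposed.
* 1.96 is used literally for 95% intervals, matching the convention the
  CIs were printed with.
* IRLS convergence at relative deviance change < 1e-8; flagged, not
  silent, on failure. Separation threshold |β| > 15.
* The intercept solver brackets α in [−50, 50] and raises if the target
  prevalence is unattainable there.
* LD-prune ordering and the bootstrap are fully deterministic given a
  seed; CLI runs log the seed, a config hash and library versions.
* Reference-study problem sizes: 676 samples, 18 + 22 loci, 20
  simulation replicates, B = 1000 bootstrap — chosen to estimate the
  seed-averaged AUC to ≈ 0.2 percentage points and the NRI to ≈ 0.02
  while keeping a full reproduction run in seconds on one CPU.

## Known limitations

* In-sample AUC is optimistic relative to external validation; that is
  a property of the emulated design, preserved deliberately.
* The null-padding comparison (18-locus vs 40-locus score) is sensitive
  to the weight given to no-signal loci: raw-OR weights ≥ 1 make null
  loci pure noise of non-trivial variance, so the extended score's
  predictions are attenuated and its NRI against the compact score is
  systematically negative — more negative than the near-zero value the
  emulated study reports for its own (unpublished) 40-variant weights.
* The Gaussian-copula LD injector targets pairwise r² only and cannot
  exceed the Fréchet correlation bound at unequal frequencies.
* No population-structure correction, genomic control or mixed models:
  the cohort is treated as homogeneous, as in the emulated design.
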