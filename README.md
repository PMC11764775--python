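# metspgs

A case-control polygenic score pipeline for metabolic syndrome (MetS),
built for biostatisticians and genetic epidemiologists who want every
stage of a small-panel risk-score study — simulation, association,
scoring, model evaluation — as tested, composable Python.

Metabolic syndrome is the clustering of visceral obesity, dyslipidemia,
elevated blood pressure and impaired glucose tolerance. Candidate-gene
studies of MetS genotype a few dozen variants in a case-control cohort,
test each under the additive genetic model, and fold the significant
loci into a polygenic score whose prognostic value is then judged by ROC
analysis and reclassification statistics. This package implements that
entire workflow, together with a synthetic-cohort generator so every
stage is testable without access to individual-level data.

## The statistics at the core

**Per-variant association.** For effect-allele dosage
*g* ∈ {0, 1, 2}, logistic regression

  logit P(case) = β₀ + β·g + β_age·age + β_sex·sex

gives the per-allele odds ratio OR = exp(β) with Wald 95% CI
exp(β ± 1.96·se). Protective fits (OR < 1) are re-fit with the
alternative allele as reference (g → 2 − g), so reported ORs are on the
risk-allele scale. Multiple testing is controlled by the
Benjamini–Hochberg step-up with an explicit family size *m*:

  p̃₍ᵢ₎ = min(1, min_{j ≥ i} m·p₍ⱼ₎ / j),

which lets the printed subset of a larger genotyped panel be adjusted
against the full panel size. Genotyping quality is screened by the
exact Hardy–Weinberg test (conditional hypergeometric-type distribution
of the heterozygote count) in controls.

**Polygenic scores.** Weighted score Σᵢ wᵢ·gᵢ with wᵢ the
age/sex-adjusted OR of locus *i*; unweighted score Σᵢ gᵢ (risk-allele
count). Same-chromosome variants with dosage r² above a threshold are
pruned, keeping the stronger association.

**Model evaluation.** Nested logistic risk models (age+sex; score;
score+age+sex) are compared by

* in-sample AUC — the midrank Mann–Whitney statistic, with 95% CI from
  the DeLong structural-components variance;
* category-free net reclassification improvement —
  NRI = P(up|case) − P(down|case) + P(down|control) − P(up|control)
  for the sign of the predicted-risk change between models, with
  standard error and percentile CI from a bootstrap stratified by
  case/control status.

The packaged 18-locus MetS panel (`metspgs.load_mets_loci()`) carries
group-specific minor-allele frequencies and published per-allele odds
ratios, and drives the reference study emulation: 279 cases and 397
controls drawn under within-group Hardy–Weinberg equilibrium, age
~ Normal(55, 10) truncated to [18, 90] and sex ~ Bernoulli(0.5)
independent of status.

## Worked example

`examples/04_risk_models.py` runs the full study emulation (simulate →
score → evaluate) and prints:

```
model discrimination (in-sample AUC, DeLong 95% CI):
  unweighted               AUC  83.1%  (80.1-86.1%)
  weighted                 AUC  84.5%  (81.6-87.4%)
  unweighted+age+sex       AUC  83.8%  (80.8-86.7%)
  weighted+age+sex         AUC  85.0%  (82.1-87.8%)
  age+sex                  AUC  52.6%  (48.1-57.0%)
  full_weighted+age+sex    AUC  78.9%  (75.5-82.3%)

reclassification (category-free NRI, bootstrap 95% CI):
  pgs_vs_covariates  total +1.036  (event +0.484, non-event +0.552)  95% CI (+0.91, +1.16)  p = 1.10e-53
  full_vs_subset     total -0.767  (event -0.376, non-event -0.390)  95% CI (-0.91, -0.62)  p = 7.16e-26
```

Reading: the OR-weighted 18-locus score alone discriminates cases from
controls with AUC in the mid-80s% (the "very good" 80–90% band); age and
sex, simulated independent of status, are null predictors (AUC ≈ 50%)
and add little to the score. Moving from the covariate-only model to
the score model moves most cases' predicted risk up and most controls'
down (total NRI ≈ +1 on the continuous scale, bounded by ±2). Padding
the score with 22 no-signal loci dilutes it — the full-panel model's
AUC drops and its NRI against the 18-locus model is clearly negative.

The other examples cover cohort simulation against the panel
frequencies (01), the association scan with FDR control (02), LD
pruning and score construction (03), and prospective-model parameter
recovery (05). A thin CLI wraps the same stages:

```bash
metspgs pipeline --seed 1 --out results/
metspgs simulate --seed 1 --out cohort.raw
metspgs assoc --genotypes cohort.raw --out assoc.tsv
```

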