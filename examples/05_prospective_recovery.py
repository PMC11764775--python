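"""Generative check: the association step recovers a known odds ratio.

Simulates disease status from the additive logistic liability
logit P(case) = alpha + log(OR) * dosage at OR = 2.0 (intercept solved
for 30% prevalence), sub-samples a case-control cohort, and re-estimates
the OR retrospectively.
"""

from metspgs import (
    CohortConfig,
    VariantSpec,
    fit_logistic_additive,
    simulate_prospective,
)

variant = VariantSpec("rs_demo", "DEMO", "1", "A", "G", 0.30, 0.30)
cohort = CohortConfig(n_case=279, n_control=397, prevalence=0.30)

covered = 0
n_rep = 50
for s in range(n_rep):
    ds = simulate_prospective([variant], cohort, {"rs_demo": 2.0},
                              seed=1000 + s, pool_factor=6)
    r = fit_logistic_additive(ds, "rs_demo")
    covered += r.ci_low < 2.0 < r.ci_high
    if s < 5:
        print(f"replicate {s}: OR = {r.or_:.2f}  "
              f"95% CI ({r.ci_low:.2f}-{r.ci_high:.2f})  p = {r.p:.1e}")

print(f"...\nWald 95% CI covered the generating OR = 2.0 in "
      f"{covered}/{n_rep} replicates.")
print("Coverage near 95% shows the retrospective additive-model fit is a "
      "consistent estimator of the prospective generative effect — the "
      "case-control design does not bias the per-allele OR.")
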