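"""Risk-model evaluation: ROC/AUC and net reclassification improvement.

Runs the full study emulation: simulates the 279/397 cohort, scores it
with the published ORs as weights, fits the nested logistic models and
compares them by in-sample AUC (DeLong 95% CI) and continuous NRI
(stratified bootstrap).
"""

from metspgs import run_reference_study

report = run_reference_study(seed=5, n_null=22, bootstrap_b=1000)

print("model discrimination (in-sample AUC, DeLong 95% CI):")
for name, m in report["models"].items():
    print(f"  {name:<24} AUC {m['auc_pct']:5.1f}%  "
          f"({m['ci_low_pct']:.1f}-{m['ci_high_pct']:.1f}%)")

print("\nreclassification (category-free NRI, bootstrap 95% CI):")
for name, c in report["comparisons"].items():
    print(f"  {name:<18} total {c['total']:+.3f}  "
          f"(event {c['event']:+.3f}, non-event {c['nonevent']:+.3f})  "
          f"95% CI ({c['ci_low']:+.2f}, {c['ci_high']:+.2f})  p = {c['p']:.2e}")

print("\nThe OR-weighted score model discriminates in the low 80s% AUC "
      "(very good band); age and sex, simulated independent of status, add "
      "almost nothing. Moving from the covariate-only model to the score "
      "model reclassifies most cases upward and most controls downward "
      "(total NRI near +1). Padding the score with 22 no-signal loci at "
      "weight 1.2 dilutes it: the negative NRI quantifies the damage.")
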