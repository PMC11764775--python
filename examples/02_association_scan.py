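"""Per-variant additive-model association scan with FDR control.

Fits logistic status ~ dosage + age + sex per locus, flips protective
fits onto the risk-allele scale, attaches control-group Hardy-Weinberg
exact-test p-values, and adjusts the p-values by Benjamini-Hochberg
against the full 40-variant panel size.
"""

from metspgs import (
    CohortConfig,
    association_scan,
    load_mets_loci,
    simulate_retrospective,
)

panel = load_mets_loci()
dataset = simulate_retrospective(panel, CohortConfig(), seed=2)

results = association_scan(dataset, m_total=40)

print(f"{'variant':<12}{'risk allele':>12}{'OR':>7}{'95% CI':>16}"
      f"{'P':>11}{'P_FDR':>11}{'P_HWE':>8}")
for r in sorted(results, key=lambda r: r.p):
    ci = f"({r.ci_low:.2f}-{r.ci_high:.2f})"
    print(f"{r.variant_id:<12}{r.effect_allele_used:>12}{r.or_:>7.2f}{ci:>16}"
          f"{r.p:>11.2e}{r.p_fdr:>11.2e}{r.hwe_p:>8.3f}")

n_sig = sum(r.p_fdr < 0.05 for r in results if r.ok)
print(f"\n{n_sig}/18 loci significant at P_FDR < 0.05 (family size 40).")
print("ORs are per effect allele, >= 1 after risk-allele flipping; P_HWE is "
      "the exact Hardy-Weinberg test in controls (large values = no "
      "genotyping-artifact signal).")
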