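"""Simulate a case-control genotype cohort at published allele frequencies.

Draws 279 cases and 397 controls at the packaged 18-locus metabolic-
syndrome panel, each locus under Hardy-Weinberg equilibrium at its
group-specific effect-allele frequency, and checks the empirical
frequencies against the generating ones.
"""

from metspgs import CohortConfig, load_mets_loci, simulate_retrospective

panel = load_mets_loci()
cohort = CohortConfig(n_case=279, n_control=397)
dataset = simulate_retrospective(panel, cohort, seed=1)

print(f"simulated {dataset.n_samples} samples x {dataset.n_variants} variants")
print(f"{'variant':<12}{'gene':<10}{'EAF ctrl (gen)':>15}{'EAF ctrl (emp)':>15}"
      f"{'EAF case (gen)':>15}{'EAF case (emp)':>15}")
for v in panel[:6]:
    emp_ctrl = dataset.empirical_eaf(v.variant_id, "control")
    emp_case = dataset.empirical_eaf(v.variant_id, "case")
    print(f"{v.variant_id:<12}{v.gene:<10}{v.eaf_control:>15.3f}{emp_ctrl:>15.3f}"
          f"{v.eaf_case:>15.3f}{emp_case:>15.3f}")
print("...")
print("Empirical effect-allele frequencies track the generating values to "
      "within binomial sampling noise (~0.02 at these group sizes); the "
      "case/control gaps are the association signal every later stage uses.")
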