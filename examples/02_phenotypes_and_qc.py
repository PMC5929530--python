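"""Dichotomize toxicity grades and run the genotype QC chain.

The four outcomes: DMN (severe diarrhoea/mucositis/neutropenia, all
patients), DM, HFS (grade 2-3) and severe HFS (grade 3), the last three in
the Capecitabine subgroup only.  QC then applies the call-rate and exact
Hardy-Weinberg filters, a PI_HAT relatedness scan, and exclusion of carriers
of listed risk variants (standing in for the four DPYD toxicity alleles).
"""

import numpy as np

import toxassoc as tx

bundle = tx.simulate_cohort(tx.CohortSpec(n_samples=504, n_variants=2000, seed=2))

print("Cohort characteristics (affected / unaffected per outcome):")
print(tx.outcome_summary(bundle.samples)[["affected_n", "unaffected_n",
                                          "excluded_n"]])

print("\nExact HWE test p-values:")
print(f"  balanced (25 hom/50 het/25 hom): {tx.hwe_exact_test(25, 50, 25):.3f}")
print(f"  het excess (10/80/10):           {tx.hwe_exact_test(10, 80, 10):.2e}")

qced, report = tx.filter_variants(bundle)
qced, sreport = tx.filter_samples(qced)
for step in report.steps + sreport.steps:
    print(f"  {step['filter']:>20s}: removed {step['removed']} "
          f"of {step['tested']} (threshold {step['threshold']})")

# carrier exclusion: any observed copy of a listed risk allele removes the
# sample, as done for the DPYD variants before association testing
risk = [qced.variants.index[10]]
after, creport = tx.exclude_known_risk_carriers(qced, risk)
print(f"risk-carrier exclusion at {risk[0]}: "
      f"{creport.steps[0]['removed']} carriers removed, "
      f"{after.n_samples} samples remain")
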