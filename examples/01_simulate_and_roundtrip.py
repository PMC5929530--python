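"""Simulate a small toxicity cohort and round-trip it through PLINK files.

Builds a 200-sample cohort with an MHC-like dense-LD region, writes it as a
.bed/.bim/.fam fileset plus a grade TSV, reads it back and verifies the
genotypes survived bit-exactly.
"""

import tempfile
from pathlib import Path

import numpy as np

import toxassoc as tx

spec = tx.CohortSpec(n_samples=200, n_variants=800, seed=1)
bundle = tx.simulate_cohort(spec)
print(f"cohort: {bundle.n_samples} samples x {bundle.n_variants} variants, "
      f"{int(bundle.variants['in_region'].sum())} in the MHC stand-in region")
print(f"missing genotype fraction: {(bundle.genotypes == tx.MISSING).mean():.4f}")

with tempfile.TemporaryDirectory() as d:
    prefix = Path(d) / "cohort"
    tx.write_plink(bundle, prefix)
    again = tx.read_plink(prefix)
    sizes = {p.suffix: p.stat().st_size for p in Path(d).iterdir()}
    print(f"wrote {sizes}; bit-exact roundtrip: "
          f"{np.array_equal(bundle.genotypes, again.genotypes)}")

# The grade columns joined onto the sample table are NCI-CTC grades 0-4;
# 'treatment' records 5FU monotherapy vs the Capecitabine pro-drug.
print(bundle.samples[["treatment", "diarrhoea", "mucositis",
                      "neutropenia", "hfs"]].head())
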