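#!/usr/bin/env python
"""Generate the synthetic study: toy genome, recombination map with
hotspots, GWAS SNP catalogue, annotation tracks, twin cohort with MZ/DZ
pairs and longitudinal repeats, and the windows x samples RPM matrix with
planted age / genotype / interaction / cell-composition effects."""
from common import get_run, report

run = get_run(__doc__)
summary = run.simulate()
report("simulate", summary)
print(f"\nWrote cohort, genotypes, methylation matrix and tracks to {run.dir}.")
print("The planted truth table (truth.tsv) is the ground truth every later",
      "step is judged against.")
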