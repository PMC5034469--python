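#!/usr/bin/env python
"""Region-set enrichment of the a-DMRs against the LD-block background
windows: CpG islands, chromatin-state composition, per-tissue DHS log2
folds with blood classification, disease-class mapping, and the
age-related-disease Fisher test with a 1000-draw permutation null."""
from common import get_run, report

run = get_run(__doc__)
summary = run.enrichment()
report("enrich", summary)
ad = summary.get("age_disease", {})
if ad:
    print(f"\nAge-related disease: OR = {ad['odds_ratio']:.2f} "
          f"(Fisher p = {ad['fisher_p']:.3f}), permutation empirical "
          f"p = {ad['empirical_p']:.3f} over {ad['n_permutations']} draws.")
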