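#!/usr/bin/env python
"""Per-window age EWAS: >=90% non-zero filter, per-window z-scoring, then a
linear mixed model (age + SNP allelic count + smoking + batch + leukocyte
fractions; family and twin-pair random intercepts) with a 1-df
likelihood-ratio test for the age term and Bonferroni control over all
tested windows."""
from common import get_run, report

run = get_run(__doc__)
summary = run.ewas()
report("ewas", summary)
print(f"\n{summary['n_significant']} of {summary['n_windows_tested']} windows "
      f"pass the Bonferroni threshold {summary['bonferroni_threshold']:.3g}.")
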