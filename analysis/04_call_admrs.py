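#!/usr/bin/env python
"""Merge Bonferroni-significant windows that overlap or are book-ended and
share the direction of the age effect into discrete a-DMRs; summarise the
hyper/hypo split, sizes and CpG content."""
from common import get_run, report

run = get_run(__doc__)
summary = run.call_dmrs()
report("call-dmrs", summary)
print(f"\n{summary['n_admrs']} a-DMRs "
      f"({100 * summary['frac_hyper']:.1f}% hyper / "
      f"{100 * summary['frac_hypo']:.1f}% hypomethylated with age), "
      f"mean size {summary['mean_size_kb']:.2f} kb, "
      f"{summary['total_cpgs']} CpGs in total.")
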