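#!/usr/bin/env python
"""Partition the genome into LD blocks at 10 cM/Mb recombination
boundaries, keep blocks holding a catalogue SNP at p < 1e-7, and enumerate
the 500-bp/250-slide analysis windows fully contained in them (removing
blacklist-overlapping windows)."""
from common import get_run, report

run = get_run(__doc__)
summary = run.blocks()
report("blocks", summary)
print(f"\n{summary['n_distinct_blocks']} GWAS LD blocks cover "
      f"{100 * summary['genome_fraction']:.1f}% of the toy genome; "
      f"{summary['n_windows']} windows enter the EWAS "
      f"({summary['n_blacklist_removed']} removed by the blacklist).")
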