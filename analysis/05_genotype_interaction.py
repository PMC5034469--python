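#!/usr/bin/env python
"""Test each window for a genotype x age interaction (facilitated, rather
than obligatory, epigenetic change) by comparing the full model with and
without the interaction term, then intersect nominally significant windows
with the called a-DMRs."""
from common import get_run, report

run = get_run(__doc__)
summary = run.interaction()
report("interact", summary)
print(f"\n{summary['n_admrs_with_interaction']} a-DMRs co-locate with a "
      f"nominally significant genotype x age interaction.")
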