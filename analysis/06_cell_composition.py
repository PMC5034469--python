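#!/usr/bin/env python
"""Guard against leukocyte-composition confounding: blood-trait-discordant
MZ twin EWAS over six cell traits, enrichment comparison of a-DMR windows
against the background, and overlap of a-DMRs with known leukocyte DMPs."""
from common import get_run, report

run = get_run(__doc__)
summary = run.cell_composition()
report("cells", summary)
verdict = "no" if summary["chi2_p"] > 0.05 else "possible"
print(f"\n{100 * summary['frac_all']:.2f}% of all windows vs "
      f"{100 * summary['frac_admr']:.2f}% of a-DMR windows show a blood-trait "
      f"association (chi2 p = {summary['chi2_p']:.3f}): {verdict} evidence of "
      f"cell-composition confounding. "
      f"{summary['n_admrs_overlapping_ldmp']} a-DMRs overlap an L-DMP.")
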