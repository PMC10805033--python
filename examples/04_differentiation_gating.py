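"""Clock-phase gating of heterocyst differentiation.

The onset of autofluorescence decay in a differentiating cell is the
stitching point of a constant-then-parabola fit; the onset is mapped to a
phase of the cell's expression cycle (0 and 1 are consecutive minima).  With
events gated at phase 0.6, the recovered phase histogram concentrates there.
"""

import numpy as np

from cyanoclock.validation import gating_recovery_experiment

out = gating_recovery_experiment(seed=1, n_events=45, n_boot=1000)
print(f"events analysed: {out['n_events']} "
      f"(of {out['n_events_simulated']} simulated)")
print(f"circular mean phase: {out['circular_mean']:.3f} (gate centre 0.6)")
print(f"resultant length:    {out['resultant_length']:.3f} (1 = perfectly narrow)")
print(f"modal histogram bin: [{out['modal_bin_left_edge']:.1f}, "
      f"{out['modal_bin_left_edge'] + 0.1:.1f})")
print(f"mean bootstrap SE per bin: {out['mean_bootstrap_se']:.3f}")
# A resultant length near 1 with the modal bin at the configured centre shows
# that differentiation onsets are confined to a narrow clock-phase window.
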