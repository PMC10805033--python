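"""Sequential expression turnoff along a vegetative interval.

In the rise-hold-decay waveform, the per-cycle decay of clock-reporter
expression starts later the farther a cell sits from its bounding
heterocysts.  Turnoff times are stitch points of constant-then-parabola fits
on the post-peak segment of each cycle; the gradient is the least-squares
slope of turnoff time against distance, averaged over (interval, cycle)
groups.
"""

from cyanoclock.validation import turnoff_recovery_experiment

for delay in (0.5, 0.0):
    slope, n_groups = turnoff_recovery_experiment(seed=2, delay=delay)
    print(f"configured delay {delay:.1f} h/cell -> recovered slope "
          f"{slope:+.3f} h/cell over {n_groups} interval-cycle groups")
# A positive slope matching the configured delay reproduces the observation
# that cells near the middle of an interval turn off last; the zero-delay
# control shows the estimator has no positional artefact.
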