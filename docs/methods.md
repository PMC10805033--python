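# Methods

This note documents the models, estimators, defaults, and numerical choices
behind `cyanoclock`, and what the synthetic-data experiments do and do not
demonstrate.

## Data model

Input is a long-format CSV with one row per cell per frame: `time_h,
filament_id, cell_id, parent_id, pos_index, cell_type, gfp, af, area`.
Times sit on a constant grid (default 0.5 h, the usual 30-min imaging
cadence); `pos_index` is the 0-based left-to-right order within the filament
at that frame and is re-assigned after divisions, so lineage (`parent_id`
links), not position, is the stable key. Cell types move only forward along
a lineage: vegetative → differentiating → heterocyst.

`resolve_lineages` splices per-frame records into per-lineage time series.
The default `concentration` policy divides total fluorescence by cell area
before splicing, because total per-cell fluorescence halves at division and
would corrupt temporal variances computed over a cycle; `first_daughter`
(raw totals, following the daughter with the smaller position index) and
`sum` (totals over all descendants) are available for sensitivity checks.
Whether published synchronization values were computed on totals or
concentrations is generally not stated by microscopy studies; concentration
is this package's default and all statistics accept either.

`intervals_at` partitions each frame into maximal runs of non-heterocyst
cells. Distance to a heterocyst is counted in cells (1 = adjacent) and is
undefined (NaN) in stretches bounded by a filament end.

## Synthetic filaments

The generator emulates the statistical regime of nitrogen-deprived
filaments, not the underlying gene network (no Kai oscillator or
HetR/PatS/HetN dynamics). Each filament is H (V×L H)×n with interval lengths
L uniform on 10–15. Per cell the clock-reporter signal is

    GFP_i(t) = [ B + A_i · w( 2π t / T_j + φ_j + ε_i ) ] · E_i · η_i(t)

with baseline B = 1000 a.u., vegetative amplitude A = 500 a.u., interval
phase φ_j (uniform on [0, 2π) per interval in the nitrogen-deprived regime;
one filament-wide draw in the replete regime), per-cell phase jitter ε_i ~
N(0, 0.25 rad), static extrinsic scale E_i (lognormal, CV 0.10), and
per-frame multiplicative measurement noise η (lognormal, CV 0.05). The
period T_j ~ N(21 h, 1 h) is drawn once per *coherence unit* — the
vegetative interval under deprivation, the filament under repletion — so
that within-unit coherence persists over multi-day recordings; per-cell
period draws would dephase an interval by several hours within three cycles,
contradicting the regime the generator is meant to emulate. Initial
(pattern) heterocysts get independent phase and period draws and oscillate
with amplitude A/5.

Two waveforms `w` are provided. `cosine` (−cos of the cycle angle; minimum
at angle 0) is the analytic default used by the recovery experiments.
`rise_hold_decay` is the realism mode for turnoff analysis: linear rise over
30% of the cycle, hold at the peak, then a parabolic decay of fixed 35%
duration whose start is delayed by `turnoff_delay_per_cell × distance` (in
hours, capped at 20% of the cycle), followed by a floor at the trough. The
decay keeps its shape as it is delayed — distant cells turn off later, not
faster — which matches the observed parallel, position-staggered decays and
keeps the turnoff estimator's small late-bias uniform across positions.

Differentiation events occur per interval and cycle (cycles 2–4, probability
0.15 by default) in a cell drawn uniformly beyond the suppression radius
(default 1 cell) of existing or newly committed heterocysts. The event time
is placed so the cell's clock phase at onset is wrapped-Normal(0.6, 0.05) in
cycle fractions; the gating family is a modeling choice (only a histogram is
typically observable). From the onset, AF falls as B_AF − c(t − t_on)² with
c = 15 a.u./h² (AF halves in ≈ 6 h at B_AF = 1000), clipped at 5% of
baseline; GFP amplitude ramps to the heterocyst level over a 12-h maturation
with the phase inherited from the progenitor. With division enabled
(default off, to keep variance structure clean), lifetimes are N(doubling
time, 10%), areas halve, and totals split binomially (p = 0.5) to mimic
partitioning noise.

Reproducibility: one root seed; per-filament child seeds by fixed
arithmetic, so any filament can be regenerated in isolation and identical
configs give byte-identical CSVs.

## Synchronization, noise, correlations

`sync_index` uses sample variances (n−1) in both numerator and denominator,
so R ≤ 1 holds exactly; the window is half-open `[t0, t1)` so that an
integer-period window of a sinusoid covers each phase exactly once (this is
what makes the closed-form check R = |Σe^{iφ}/n|² exact). Group composition
follows the 8–11-cell protocol: contiguous groups are the centermost ≤ 11
cells of a bounded interval with ≥ 8 vegetative cells; separated groups take
one centre cell per interval (ties toward the left heterocyst). The cycle
window is delimited by two consecutive fitted minima of the group-mean
trace; when the group mean is too flat to carry minima (desynchronized
separated groups), a one-period window starting a quarter period into the
trace is used instead — for equal-period oscillators R over a full period
does not depend on the window origin. No detrending or smoothing is applied
before R.

Noise (CV²) and the neighbour/cross-interval Pearson correlations are
evaluated at frames nearest to 1/4 and 3/4 of each cycle, where
cell-to-cell spread is maximal. Cross-interval pairs index cells outward
from the shared bounding heterocyst and truncate to the shorter interval.

## Minima, period, amplitude, turnoff

Candidate minima come from local minima of a 5-frame moving mean, separated
by ≥ half the expected period and at least 10% of a period away from the
trace ends (one-sided windows produced unreliable refinements). Each
candidate is refined on the raw data over ± 20% of the expected period by
the lower-SSE of (a) a single upward parabola, vertex inside the window, or
(b) a continuous piecewise line/parabola pair constrained to fall into and
rise out of the stitch, whose stitch point is the refined time. The
parameter-count difference (3 vs 4) is ignored in the SSE comparison; the
monotonicity constraints keep the richer model from winning on noise alone.
The fit-window fraction (± 20%) is this package's convention.

Periods are means of consecutive minima spacings; cohort summaries are mean
± SE over traces. Amplitude is half the peak-to-trough range within one
cycle window — simple and noise-inflated, which is why the amplitude-ratio
check runs on noise-free cohorts. `align_by_event` shifts traces so their
(continuous) event times sit at 0, snapping to the nearest frame.

Turnoff times reuse the constant-then-parabola stitch on the post-peak
segment of each cycle window (relaxed to ≥ 3 pre-stitch frames, since the
peak plateau is short). Windows shorter than 0.7 or longer than 1.4 expected
periods are discarded as spurious. Because absolute times are only
comparable within one coherence unit, gradients are fit per (interval,
cycle); records are grouped by clustering turnoff times at gaps > half a
period (per-cell cycle indices can drift by one when a first minimum escapes
detection), and the reported gradient is the mean of per-group least-squares
slopes.

## AF onset and gating

`fit_constant_parabola` grid-searches the stitch over frame times and frame
midpoints; for each candidate the level and curvature solve a small linear
least-squares problem, with continuity and a zero-slope vertex at the stitch
enforced by construction (an unconstrained-slope variant sits behind
`constrain_vertex=False`). All candidates are scored on one common point
set: the trace is truncated where the signal first falls below 50% of the
pre-onset level, which both restricts the parabola to the initial stage of
the decay (before any floor) and keeps candidate SSEs comparable —
per-candidate point sets would bias the search toward early stitches. Ties
break toward the earliest stitch. A noiseless onset on the frame grid is
recovered exactly; at 5% measurement noise ≥ 95% of onsets land within 1 h.

Onset phases use the differentiating cell's own expression minima for
bracketing; events are restricted to cycles 2–4 by default (the observed
differentiation window), liftable via `cycles`. The phase histogram uses 10
equal bins on [0, 1] — wide enough that ≤ 1 h timing error stays inside one
bin at a 21-h period — with per-bin bootstrap SEs over 1,000 resamples under
a fixed seed.

## Pipeline and reports

`analyze_cohort` chains interval resolution, lineage splicing, synchrony,
oscillation features, turnoff, and gating; every reported number is produced
by exactly one library operation. Reports serialize with sorted keys and
floats at 12 significant digits, so a (traces, seed) pair yields
byte-identical JSON. Stage switches (`synchrony`, `oscillation`, `gating`,
`turnoff`) exist to keep repeated-seed experiments cheap. The CLI
(`cyanoclock simulate/analyze/recover`) is a thin layer over these
functions.

## Validation experiments and their scope

`cyanoclock.validation` holds the recovery experiments the test suite and
`scripts/acceptance.py` run. Problem sizes were chosen to keep each
experiment in the seconds-to-minutes range: 10,000 random trace sets for the
R oracle, 1,000 cohorts for the independence limit, 500 replicates for
onset recovery, 30 single-interval traces for period recovery (one cell per
interval, mirroring the sampling of independent cells), 45 events per
gating cohort (the event count of the motivating experiments) over up to 50
seeds, and 3-filament × 5-interval cohorts for turnoff gradients averaged
over three replicates.

What passing these experiments shows — and what it does not: the generator
reproduces the *statistical* structure the estimators assume (coherent
intervals, independent interval phases, gated onsets, graded turnoff), so
recovery demonstrates correctness of the estimators under realistic noise
levels, sampling cadence, and cohort sizes. It does not demonstrate
robustness to segmentation/tracking errors, photobleaching or focus drift,
non-stationary baselines, filament movement or fragmentation, or deviations
of real expression waveforms from the modeled shapes — real data carry all
of these. Known limitations: the stitch estimator has a small late bias on
shallow decays (visible as ~5–10% attenuation of the turnoff gradient);
amplitude estimates are upward-biased by noise; heterocyst period estimates
are less precise than vegetative ones because the oscillation amplitude is
5-fold smaller than the noise floor scale.
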