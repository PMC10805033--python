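# cyanoclock

Single-cell circadian trace analysis for filamentous cyanobacteria.

Under nitrogen deprivation, *Anabaena* filaments differentiate single
nitrogen-fixing heterocysts every 10–15 vegetative cells. Time-lapse
microscopy of a clock-controlled reporter (e.g. a *pecB* promoter–GFP fusion)
then raises quantitative questions that this package answers from long-format
per-cell fluorescence tables: how synchronized are the clocks of neighbouring
cells, does synchrony survive across heterocyst boundaries, when in the
circadian cycle does differentiation start, and do cells in an interval turn
expression off in a positional sequence? The library is aimed at groups doing
single-cell time-lapse analysis of bacterial gene expression who need these
statistics plus a ground-truth synthetic data generator to validate them.

## The statistics at the core

**Synchronization index.** For cells *i* with fluorescence traces
*f<sub>i</sub>(t)* and group mean *μ(t)*, evaluated over one full oscillation
period,

    R = ( ⟨μ²⟩ − ⟨μ⟩² ) / mean_i( ⟨f_i²⟩ − ⟨f_i⟩² )

where ⟨·⟩ is a time average. R = 1 for identical phases and E[R] ≈ 1/n for n
independent phases; for equal-amplitude sinusoids over an integer number of
periods, R equals the squared mean resultant length |Σ e^{iφ}/n|² of the
phase distribution.

**Expression noise.** CV² = Var(f)/mean(f)² across cells at one frame, taken
at the quarter and three-quarter points of the cycle where cell-to-cell
spread is maximal.

**Changepoint onsets.** The onset of autofluorescence (AF) decay in an
incipient heterocyst is the stitching point t₀ of a least-squares piecewise
fit: f(t) = c before t₀ and f(t) = c − a(t − t₀)² after it. Expression minima
are refined the same way, by a parabola (vertex) or a continuous
line-plus-parabola fit (stitch point), whichever has lower SSE.

**Phase of differentiation.** An onset at time t_on between consecutive
expression minima t₋ and t₊ has circadian phase (t_on − t₋)/(t₊ − t₋) ∈
[0, 1). Phases across events are summarized by a normalized histogram with
1,000-sample bootstrap error bars and by circular statistics.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/02_synchronization.py` prints:

```
nitrogen_deprived:
  mean R, contiguous 8-11-cell groups: 0.908
  mean R, one centre cell per interval: 0.055
  expression noise CV^2 (whole filament): 0.122
  Pearson r, nearest neighbours: 0.81; adjacent intervals: -0.04
nitrogen_replete:
  mean R, contiguous 8-11-cell groups: 0.912
  mean R, one centre cell per interval: 0.897
  expression noise CV^2 (whole filament): 0.031
  Pearson r, nearest neighbours: 0.23; adjacent intervals: 0.15
```

Read: under nitrogen deprivation, cells inside one heterocyst-bounded
interval stay mutually synchronized (R ≈ 0.9, high neighbour correlation)
while cells of different intervals are as desynchronized as independent
oscillators (R ≈ 1/n, near-zero cross-interval correlation) — the vegetative
interval, not the filament, is the coherent unit. In the nitrogen-replete
regime both group kinds give the same high R. Likewise,
`python examples/04_differentiation_gating.py` recovers a circular mean onset
phase of 0.640 (resultant length 0.935) for events gated at phase 0.6, and
`python examples/05_turnoff_gradient.py` recovers a +0.501 h/cell turnoff
delay gradient for a configured 0.5 h/cell.

The `cyanoclock` command wraps the same pipeline for shell use:
`cyanoclock simulate --config cfg.yaml --out sim/`,
`cyanoclock analyze --traces sim/traces.csv --out results/`, and
`cyanoclock recover --config cfg.yaml --out rec/` (ground truth vs
estimates).

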