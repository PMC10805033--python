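"""Synchronization index, expression noise, and spatial correlation structure.

The synchronization index of a group of cells is

    R = Var_t[ mu(t) ] / mean_i( Var_t[ f_i(t) ] ),

the variance over time of the group-mean fluorescence trace mu(t) divided by
the mean over cells of each cell's own temporal variance, both evaluated over
one full oscillation period.  R = 1 for identical phases, and E[R] ~ 1/n for n
independent phases; for equal-amplitude sinusoids over an integer number of
periods R equals the squared mean resultant length |sum_i e^{i phi_i} / n|^2
of the phase distribution.

Expression noise across cells at one frame is CV^2 = Var[f] / mean[f]^2, and
the spatial structure of coordination is summarized by Pearson correlations of
nearest-neighbour pairs within a vegetative interval versus pairs of
corresponding cells (counted from the shared heterocyst) in adjacent
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .trace_model import CellTrace, VegInterval, FILAMENT_END

__all__ = [
    "SynchronyError",
    "ZeroVarianceError",
    "AlignmentError",
    "DegenerateError",
    "SyncResult",
    "PairSet",
    "sync_index",
    "expression_noise",
    "neighbor_pairs",
    "interval_pairs",
    "pearson",
    "pick_quarter_times",
]


class SynchronyError(ValueError):
    pass


class ZeroVarianceError(SynchronyError):
    """A trace is constant over the analysis window."""


class AlignmentError(SynchronyError):
    """Traces do not share a common time grid over the window."""


class DegenerateError(SynchronyError):
    """Pair set has zero variance in one coordinate."""


@dataclass
class SyncResult:
    """Synchronization index with its variance components."""

    R: float
    var_of_mean: float
    mean_of_var: float
    n_cells: int
    window: tuple[float, float]


@dataclass
class PairSet:
    """Intensity pairs sampled at one frame for scatter/correlation analysis."""

    pairs: list[tuple[float, float]]
    pairing_kind: str  # "nearest_neighbor" | "adjacent_interval"
    sample_time: float

    def __len__(self) -> int:
        return len(self.pairs)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.empty(0), np.empty(0)
        arr = np.asarray(self.pairs, dtype=float)
        return arr[:, 0], arr[:, 1]


def _window_matrix(traces: Sequence[CellTrace], window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Stack trace values over the half-open window [t0, t1) on a shared grid."""
    t0, t1 = window
    ref = None
    rows = []
    for tr in traces:
        mask = (tr.times >= t0 - 1e-9) & (tr.times < t1 - 1e-9)
        tt = tr.times[mask]
        if ref is None:
            ref = tt
        elif len(tt) != len(ref) or not np.allclose(tt, ref):
            raise AlignmentError("traces are not sampled on a common grid over the window")
        rows.append(tr.gfp[mask])
    return np.asarray(ref), np.vstack(rows)


def sync_index(traces: Sequence[CellTrace] | np.ndarray, window: tuple[float, float] | None = None) -> SyncResult:
    """Synchronization index R of a group of traces over one cycle window.

    Parameters
    ----------
    traces
        Either :class:`CellTrace` objects (GFP channel is used) or a 2-D
        array of shape (n_cells, n_frames) already restricted to the window.
    window
        Half-open time span ``[t_start, t_end)``; required for CellTrace
        input, ignored for array input.

    Raises
    ------
    ZeroVarianceError
        Any trace is constant over the window.
    AlignmentError
        Trace time grids differ over the window.
    """
    if isinstance(traces, np.ndarray):
        X = np.asarray(traces, dtype=float)
        win = (0.0, float(X.shape[1])) if window is None else window
    else:
        traces = list(traces)
        if window is None:
            raise ValueError("window is required for CellTrace input")
        _, X = _window_matrix(traces, window)
        win = (float(window[0]), float(window[1]))
    if X.ndim != 2 or X.shape[0] < 2:
        raise SynchronyError("need at least 2 traces")
    if X.shape[1] < 4:
        raise SynchronyError("window must contain at least 4 frames")
    cell_vars = X.var(axis=1, ddof=1)
    if np.any(cell_vars <= 0):
        raise ZeroVarianceError("constant trace in window")
    var_of_mean = float(X.mean(axis=0).var(ddof=1))
    mean_of_var = float(cell_vars.mean())
    return SyncResult(
        R=var_of_mean / mean_of_var,
        var_of_mean=var_of_mean,
        mean_of_var=mean_of_var,
        n_cells=X.shape[0],
        window=win,
    )


def expression_noise(values: Iterable[float]) -> float:
    """Cell-to-cell expression noise CV^2 = Var / mean^2 at one frame."""
    v = np.asarray(list(values), dtype=float)
    if len(v) < 2:
        raise SynchronyError("need at least 2 values")
    m = v.mean()
    if m <= 0:
        raise SynchronyError("mean intensity must be positive")
    return float(v.var(ddof=1) / m**2)


def _values_at(traces: dict[str, CellTrace], cell_ids: Sequence[str], time: float) -> list[float]:
    out = []
    for cid in cell_ids:
        tr = traces[cid]
        idx = np.flatnonzero(np.isclose(tr.times, time))
        if len(idx) == 0:
            raise AlignmentError(f"cell {cid} has no frame at t={time}")
        out.append(float(tr.gfp[idx[0]]))
    return out


def neighbor_pairs(interval: VegInterval, traces: dict[str, CellTrace], time: float) -> PairSet:
    """(f_i, f_{i+1}) pairs of nearest-neighbour cells along one interval."""
    vals = _values_at(traces, interval.cell_ids, time)
    pairs = list(zip(vals[:-1], vals[1:]))
    return PairSet(pairs=pairs, pairing_kind="nearest_neighbor", sample_time=float(time))


def interval_pairs(
    interval_a: VegInterval,
    interval_b: VegInterval,
    traces: dict[str, CellTrace],
    time: float,
) -> PairSet:
    """(f_{i,j}, f_{i,j+1}) pairs of corresponding cells in adjacent intervals.

    Cells are indexed from the shared bounding heterocyst and pairing is
    truncated to the shorter interval.  If the two intervals do not share a
    boundary, the facing ends are used (``interval_a`` taken to the left).
    """
    ids_a, ids_b = list(interval_a.cell_ids), list(interval_b.cell_ids)
    if interval_a.bounding[1] != FILAMENT_END and interval_a.bounding[1] == interval_b.bounding[0]:
        ids_a = ids_a[::-1]  # count outward from the shared heterocyst
    elif interval_b.bounding[1] != FILAMENT_END and interval_b.bounding[1] == interval_a.bounding[0]:
        ids_b = ids_b[::-1]
    else:
        ids_a = ids_a[::-1]
    n = min(len(ids_a), len(ids_b))
    va = _values_at(traces, ids_a[:n], time)
    vb = _values_at(traces, ids_b[:n], time)
    return PairSet(pairs=list(zip(va, vb)), pairing_kind="adjacent_interval", sample_time=float(time))


def pearson(pairs: PairSet) -> float:
    """Product-moment correlation of a pair set."""
    x, y = pairs.as_arrays()
    if len(x) < 3:
        raise SynchronyError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateError("zero variance in one coordinate of the pair set")
    return float(np.corrcoef(x, y)[0, 1])


def pick_quarter_times(
    minima: Sequence[float],
    period: float,
    dt: float = 0.5,
    grid_origin: float = 0.0,
) -> list[float]:
    """Frame times at 1/4 and 3/4 of each cycle, where cell-to-cell spread peaks.

    For each detected minimum (except the last), ``t_min + period/4`` and
    ``t_min + 3 period/4`` are snapped to the nearest frame of the
    ``grid_origin + k*dt`` grid.
    """
    minima = sorted(float(m) for m in minima)
    if len(minima) < 2:
        raise SynchronyError("need at least 2 minima")
    out = []
    for m in minima[:-1]:
        for frac in (0.25, 0.75):
            t = m + frac * period
            snapped = grid_origin + round((t - grid_origin) / dt) * dt
            out.append(float(snapped))
    return out
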