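"""Circadian minima, period, amplitude, event alignment, and turnoff gradients.

Minima of the clock-reporter expression cycle are located on a lightly
smoothed trace and refined by local least-squares fits to the raw data:
either a single parabola (refined time = vertex) or a piecewise
line-plus-parabola whose stitch point supplies the refined time, whichever
has lower SSE.  Periods are means of consecutive minima spacings, pooled over
traces for a cohort mean +/- SE.  Amplitude is half the peak-to-trough range
within one cycle window; the vegetative/heterocyst amplitude ratio uses group
medians.  Per-cycle expression turnoff times (the delayed decay of the cycle
in cells far from a heterocyst) reuse the constant-then-parabola stitch fit
on the post-peak segment, and the turnoff gradient is the least-squares slope
of turnoff time against distance to the nearest bounding heterocyst.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .differentiation_timing import (
    NoOnsetError,
    OnsetError,
    fit_constant_parabola,
)

__all__ = [
    "FeatureError",
    "NoTurnoffError",
    "GradientError",
    "MinimumEstimate",
    "CycleWindow",
    "TurnoffRecord",
    "detect_minima",
    "estimate_period",
    "cycle_windows",
    "amplitude",
    "amplitude_ratio",
    "align_by_event",
    "detect_turnoff",
    "turnoff_gradient",
    "mean_turnoff_gradient",
]

SMOOTH_WINDOW_FRAMES = 5


class FeatureError(ValueError):
    pass


class NoTurnoffError(FeatureError):
    """No decay detectable within the cycle window."""


class GradientError(FeatureError):
    """Too few distinct distances for a turnoff gradient."""


@dataclass
class MinimumEstimate:
    time: float
    method: str                 # "parabola" | "parabola_linear"
    fit_window: tuple[float, float]
    sse: float


@dataclass
class CycleWindow:
    t_start: float
    t_end: float
    cycle_index: int            # 1-based


@dataclass
class TurnoffRecord:
    cell_id: str
    cycle_index: int
    turnoff_time: float
    distance_to_heterocyst: float
    interval_id: str = ""


def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def _fit_parabola(t: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """(vertex_time, sse) of an upward parabola, or None if invalid."""
    if len(t) < 4:
        return None
    coef = np.polyfit(t, y, 2)
    a, b, _ = coef
    if a <= 0:
        return None
    vertex = -b / (2 * a)
    if vertex < t[0] or vertex > t[-1]:
        return None
    sse = float(np.sum((np.polyval(coef, t) - y) ** 2))
    return float(vertex), sse


def _fit_line_parabola(t: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Piecewise line/parabola stitch fit; returns (stitch_time, sse) or None.

    The two branches meet continuously at the stitch, the left branch falls
    into it and the right branch rises out of it, so the stitch point is the
    minimum of the fitted curve.  Both orientations (line on the left,
    parabola on the right, and the mirror image) are tried at every interior
    stitch; candidates violating the falling/rising constraint are rejected.
    """
    n = len(t)
    if n < 6:
        return None
    best = None
    for s in range(2, n - 3):
        ts = t[s]
        d = t - ts
        left, right = d < 0, d > 0
        for parabola_left in (False, True):
            # y = v + bl*d (left) + br*d + c*d^2 (one side quadratic)
            A = np.zeros((n, 4))
            A[:, 0] = 1.0
            A[left, 1] = d[left]
            A[right, 2] = d[right]
            quad = left if parabola_left else right
            A[quad, 3] = d[quad] ** 2
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            _, bl, br, c = coef
            if bl > 0 or br < 0 or c < 0:
                continue  # not a trough at the stitch
            sse = float(np.sum((A @ coef - y) ** 2))
            if best is None or sse < best[1]:
                best = (float(ts), sse)
    return best


def detect_minima(
    times: Sequence[float],
    values: Sequence[float],
    expected_period: float,
) -> list[MinimumEstimate]:
    """Locate and refine the minima of a circadian trace.

    Candidates come from local minima of a 5-frame moving mean, separated by
    at least half the expected period; each is refined on the raw data over a
    window of +/- 20% of the expected period by the lower-SSE of a parabolic
    fit (vertex) or a piecewise line/parabola fit (stitch point).  A monotone
    trace yields an empty list.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 2:
        return []
    if t[-1] - t[0] < 1.5 * expected_period:
        raise FeatureError("trace must span at least 1.5 expected periods")
    s = _moving_mean(y, SMOOTH_WINDOW_FRAMES)
    interior = np.arange(1, len(s) - 1)
    is_min = (s[interior] <= s[interior - 1]) & (s[interior] <= s[interior + 1])
    cand = interior[is_min]
    # candidates hugging the trace ends have one-sided fit windows and are
    # unreliable; require 10% of a period of data on both sides
    edge = 0.1 * expected_period
    cand = cand[(t[cand] >= t[0] + edge) & (t[cand] <= t[-1] - edge)]
    # collapse plateaus and enforce separation, keeping the deepest first
    cand = cand[np.argsort(s[cand], kind="stable")]
    kept: list[int] = []
    for c in cand:
        if all(abs(t[c] - t[k]) >= 0.5 * expected_period for k in kept):
            kept.append(int(c))
    half = 0.2 * expected_period
    out: list[MinimumEstimate] = []
    for c in sorted(kept):
        mask = np.abs(t - t[c]) <= half + 1e-9
        tw, yw = t[mask], y[mask]
        if len(tw) < 5:
            continue
        fits = []
        par = _fit_parabola(tw, yw)
        if par is not None:
            fits.append(("parabola", *par))
        pl = _fit_line_parabola(tw, yw)
        if pl is not None:
            fits.append(("parabola_linear", *pl))
        if not fits:
            continue
        method, t_min, sse = min(fits, key=lambda f: f[2])
        out.append(MinimumEstimate(
            time=float(t_min), method=method,
            fit_window=(float(tw[0]), float(tw[-1])), sse=sse,
        ))
    # final pass: times may have shifted; re-enforce separation in time order
    out.sort(key=lambda m: m.time)
    sep: list[MinimumEstimate] = []
    for m in out:
        if sep and m.time - sep[-1].time < 0.5 * expected_period:
            if m.sse < sep[-1].sse:
                sep[-1] = m
        else:
            sep.append(m)
    return sep


def estimate_period(minima: Sequence) -> tuple[float, float]:
    """Mean period +/- SE from minima times.

    A flat sequence of times is treated as one trace (period = mean spacing,
    SE over spacings); a sequence of sequences is a cohort (per-trace period,
    SE over traces).
    """
    items = list(minima)
    if not items:
        raise FeatureError("no minima provided")
    if np.isscalar(items[0]) or isinstance(items[0], (int, float, np.floating)):
        diffs = np.diff(np.sort(np.asarray(items, dtype=float)))
        if len(diffs) == 0:
            raise FeatureError("need at least 2 minima")
        se = float(diffs.std(ddof=1) / np.sqrt(len(diffs))) if len(diffs) > 1 else 0.0
        return float(diffs.mean()), se
    periods = []
    for tr in items:
        tr = np.sort(np.asarray(list(tr), dtype=float))
        if len(tr) >= 2:
            periods.append(np.diff(tr).mean())
    if not periods:
        raise FeatureError("no trace has at least 2 minima")
    periods = np.asarray(periods)
    se = float(periods.std(ddof=1) / np.sqrt(len(periods))) if len(periods) > 1 else 0.0
    return float(periods.mean()), se


def cycle_windows(minima: Sequence[float]) -> list[CycleWindow]:
    """Consecutive minima pairs as 1-based cycle windows."""
    m = np.sort(np.asarray(list(minima), dtype=float))
    return [
        CycleWindow(t_start=float(a), t_end=float(b), cycle_index=i + 1)
        for i, (a, b) in enumerate(zip(m[:-1], m[1:]))
    ]


def amplitude(times: Sequence[float], values: Sequence[float], window: CycleWindow) -> float:
    """Half the peak-to-trough range of the trace within one cycle window."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    mask = (t >= window.t_start - 1e-9) & (t <= window.t_end + 1e-9)
    if not mask.any():
        raise FeatureError("window outside trace span")
    yw = y[mask]
    return float((yw.max() - yw.min()) / 2)


def amplitude_ratio(
    veg_traces: Sequence[tuple[np.ndarray, np.ndarray]],
    het_traces: Sequence[tuple[np.ndarray, np.ndarray]],
    expected_period: float = 21.0,
) -> float:
    """Median vegetative amplitude / median heterocyst amplitude.

    Each trace is a ``(times, values)`` pair; the amplitude of each trace is
    taken over its first detected full cycle, traces with fewer than two
    detectable minima are skipped.
    """
    def group_amps(traces):
        amps = []
        for t, y in traces:
            minima = detect_minima(t, y, expected_period)
            wins = cycle_windows([m.time for m in minima])
            if wins:
                amps.append(amplitude(t, y, wins[0]))
        return amps

    va, ha = group_amps(veg_traces), group_amps(het_traces)
    if not va or not ha:
        raise FeatureError("empty group after minima detection")
    return float(np.median(va) / np.median(ha))


def align_by_event(
    traces: Sequence[tuple[np.ndarray, np.ndarray]],
    event_times: Sequence[float],
    dt: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shift traces so their events coincide at time 0 and average them.

    Returns ``(rel_times, matrix, mean_trace)`` where ``matrix`` is NaN-padded
    over the union grid of shifted frame times and ``mean_trace`` averages the
    traces present at each relative time.  Event times are continuous; each
    shifted trace is placed on the grid at the nearest frame, so residual
    phase smear is below half a frame.
    """
    if len(traces) != len(event_times):
        raise FeatureError("one event time per trace required")
    shifted = []
    for (t, y), ev in zip(traces, event_times):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if ev < t[0] or ev > t[-1]:
            raise FeatureError(f"event time {ev} outside trace span")
        shifted.append((t - ev, y))
    if dt is None:
        dt = float(np.min([np.diff(t).min() for t, _ in shifted]))
    lo = min(t[0] for t, _ in shifted)
    hi = max(t[-1] for t, _ in shifted)
    rel = np.round(np.arange(round(lo / dt), round(hi / dt) + 1) * dt, 9)
    mat = np.full((len(shifted), len(rel)), np.nan)
    for i, (t, y) in enumerate(shifted):
        idx = np.round(t / dt).astype(int) - round(lo / dt)
        mat[i, idx] = y
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
    return rel, mat, mean


def detect_turnoff(
    times: Sequence[float],
    values: Sequence[float],
    window: CycleWindow,
    cell_id: str = "",
    distance_to_heterocyst: float = np.nan,
    interval_id: str = "",
) -> TurnoffRecord:
    """Turnoff time of one expression cycle: stitch of the post-peak decay.

    The trace within the cycle window must rise to a peak and then decay; the
    constant-then-parabola stitch fit is applied from the peak onward with
    relaxed pre-stitch requirements (the plateau at the peak is short).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    mask = (t >= window.t_start - 1e-9) & (t <= window.t_end + 1e-9)
    tw, yw = t[mask], y[mask]
    if len(tw) < 8:
        raise NoTurnoffError("cycle window too short")
    peak = int(np.argmax(_moving_mean(yw, 3)))
    tseg, yseg = tw[peak:], yw[peak:]
    try:
        est = fit_constant_parabola(tseg, yseg, min_pre=3, min_post=4)
    except OnsetError as e:
        raise NoTurnoffError(f"no decay within window: {e}") from e
    return TurnoffRecord(
        cell_id=cell_id,
        cycle_index=window.cycle_index,
        turnoff_time=est.t_on,
        distance_to_heterocyst=float(distance_to_heterocyst),
        interval_id=interval_id,
    )


def turnoff_gradient(records: Sequence[TurnoffRecord]) -> float:
    """Least-squares slope (h/cell) of turnoff time vs distance to heterocyst.

    The records must come from one vegetative interval and one cycle —
    absolute turnoff times from intervals with independent clock phases are
    not comparable.  See :func:`mean_turnoff_gradient` for pooling.
    """
    recs = [r for r in records if np.isfinite(r.distance_to_heterocyst)]
    if len(recs) < 2:
        raise GradientError("need at least 2 records with finite distances")
    x = np.asarray([r.distance_to_heterocyst for r in recs], dtype=float)
    y = np.asarray([r.turnoff_time for r in recs], dtype=float)
    if len(np.unique(x)) < 2:
        raise GradientError("need at least 2 distinct distances")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def mean_turnoff_gradient(
    records: Sequence[TurnoffRecord],
    expected_period: float = 21.0,
    min_records: int = 4,
) -> tuple[float, int]:
    """Pooled turnoff gradient over (interval, cycle) groups; returns (slope, n_groups).

    Records of one interval are clustered into cycles by splitting the sorted
    turnoff times at gaps larger than half a period (per-cell cycle indices
    can drift by one when a trace's first minimum escapes detection, so
    absolute-time clustering is the reliable grouping).  The reported slope
    is the mean of per-group least-squares slopes.
    """
    by_interval: dict[str, list[TurnoffRecord]] = {}
    for r in records:
        by_interval.setdefault(r.interval_id, []).append(r)
    slopes = []
    for recs in by_interval.values():
        recs = sorted(recs, key=lambda r: r.turnoff_time)
        cluster: list[TurnoffRecord] = []
        clusters = []
        for r in recs:
            if cluster and r.turnoff_time - cluster[-1].turnoff_time > 0.5 * expected_period:
                clusters.append(cluster)
                cluster = []
            cluster.append(r)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            if len(cl) < min_records:
                continue
            try:
                slopes.append(turnoff_gradient(cl))
            except GradientError:
                continue
    if not slopes:
        raise GradientError("no (interval, cycle) group with enough records")
    return float(np.mean(slopes)), len(slopes)
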