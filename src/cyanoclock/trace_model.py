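"""Canonical data model for filament time-lapse traces.

A *filament series* is the long-format record of one cyanobacterial filament
followed by time-lapse microscopy: one row per cell per frame, carrying the
cell's position along the filament, its type (vegetative / differentiating /
heterocyst), total GFP reporter fluorescence, photosynthetic-pigment
autofluorescence (AF), and segmented cell area.  Lineage is encoded through
``parent_id`` links; position indices are re-assigned every frame (cells shift
when neighbours divide), so lineage, not position, is the stable key.

This module provides the CSV reader/writer for that schema, lineage
resolution into per-cell time series (:class:`CellTrace`), and per-frame
decomposition of a filament into heterocyst-bounded vegetative intervals
(:class:`VegInterval`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES",
    "TRACES_COLUMNS",
    "FILAMENT_END",
    "TraceError",
    "SchemaError",
    "SamplingError",
    "IntegrityError",
    "LineageError",
    "FilamentSeries",
    "CellTrace",
    "VegInterval",
    "read_traces",
    "write_traces",
    "resolve_lineages",
    "intervals_at",
]

#: Ordered cell types; transitions along a lineage may only move rightward.
CELL_TYPES = ("vegetative", "differentiating", "heterocyst")
_TYPE_RANK = {t: i for i, t in enumerate(CELL_TYPES)}

#: Exact column set of the traces CSV schema.
TRACES_COLUMNS = [
    "time_h",
    "filament_id",
    "cell_id",
    "parent_id",
    "pos_index",
    "cell_type",
    "gfp",
    "af",
    "area",
]

#: Marker used for the missing bounding heterocyst of an end-bounded interval.
FILAMENT_END = "filament_end"


class TraceError(ValueError):
    """Base class for trace-model validation errors."""


class SchemaError(TraceError):
    """The file does not match the traces CSV schema."""


class SamplingError(TraceError):
    """Frame times are not a constant-step grid."""


class IntegrityError(TraceError):
    """Record-level invariant violated (positions, duplicates, types)."""


class LineageError(TraceError):
    """Parent links are inconsistent (orphan cells, missing parents)."""


@dataclass
class FilamentSeries:
    """All per-frame snapshots of one filament, as a validated long table.

    Parameters
    ----------
    filament_id
        Identifier shared by every record.
    frames
        DataFrame with :data:`TRACES_COLUMNS`, one row per cell per frame.
        ``parent_id`` is ``None`` for founder cells.
    """

    filament_id: str
    frames: pd.DataFrame

    def __post_init__(self) -> None:
        self.frames = self.frames.sort_values(["time_h", "pos_index"]).reset_index(drop=True)
        _validate_filament(self.filament_id, self.frames)

    @property
    def times(self) -> np.ndarray:
        """Sorted unique frame times (hours)."""
        return np.sort(self.frames["time_h"].unique())

    @property
    def dt(self) -> float:
        """Constant sampling step in hours."""
        t = self.times
        if len(t) < 2:
            raise SamplingError("need at least two frames to infer a sampling step")
        return float(t[1] - t[0])

    def at(self, time: float) -> pd.DataFrame:
        """Rows of the frame at ``time``, ordered by position."""
        sub = self.frames[np.isclose(self.frames["time_h"], time)]
        if sub.empty:
            raise SamplingError(f"{time} is not a sampled frame of filament {self.filament_id}")
        return sub.sort_values("pos_index")

    def n_records(self) -> int:
        return len(self.frames)


@dataclass
class CellTrace:
    """One lineage-resolved time series of GFP and AF intensities.

    ``interval_id_per_frame`` and ``distance_to_heterocyst_per_frame`` record,
    frame by frame, which vegetative interval the (followed) cell belongs to
    and how many cells separate it from the nearest bounding heterocyst
    (1 = adjacent; NaN when the stretch is bounded by a filament end;
    0 for a heterocyst itself).
    """

    cell_id: str
    times: np.ndarray
    gfp: np.ndarray
    af: np.ndarray
    interval_id_per_frame: np.ndarray
    distance_to_heterocyst_per_frame: np.ndarray
    cell_type_per_frame: np.ndarray
    filament_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("gfp", "af", "interval_id_per_frame",
                     "distance_to_heterocyst_per_frame", "cell_type_per_frame"):
            if len(getattr(self, name)) != n:
                raise IntegrityError(f"{name} length does not match times")
        dts = np.diff(self.times)
        if n >= 2 and (np.any(dts <= 0) or not np.allclose(dts, dts[0])):
            raise SamplingError("trace times must be strictly increasing with constant step")


@dataclass
class VegInterval:
    """A maximal run of non-heterocyst cells at one frame.

    ``bounding`` holds the cell ids of the flanking heterocysts, with
    :data:`FILAMENT_END` standing in when the run touches a filament end.
    """

    interval_id: str
    filament_id: str
    time: float
    cell_ids: list[str]
    bounding: tuple[str, str]

    @property
    def end_bounded(self) -> bool:
        return FILAMENT_END in self.bounding

    def __len__(self) -> int:
        return len(self.cell_ids)


# ---------------------------------------------------------------------------
# validation

def _validate_filament(filament_id: str, df: pd.DataFrame) -> None:
    if (df["filament_id"] != filament_id).any():
        raise IntegrityError("mixed filament ids inside one FilamentSeries")
    if (df["time_h"] < 0).any():
        raise IntegrityError("negative frame times")
    if (df["gfp"] < 0).any() or (df["af"] < 0).any():
        raise IntegrityError("negative intensities")
    if (df["area"] <= 0).any():
        raise IntegrityError("non-positive cell areas")
    bad_type = ~df["cell_type"].isin(CELL_TYPES)
    if bad_type.any():
        raise IntegrityError(f"unknown cell_type values: {sorted(df.loc[bad_type, 'cell_type'].unique())}")

    for t, frame in df.groupby("time_h", sort=True):
        pos = np.sort(frame["pos_index"].to_numpy())
        if not np.array_equal(pos, np.arange(len(frame))):
            raise IntegrityError(
                f"pos_index at t={t} of filament {filament_id} is not a contiguous 0..n-1 run"
            )
        if frame["cell_id"].duplicated().any():
            raise IntegrityError(f"duplicate cell_id at t={t} of filament {filament_id}")

    # cell_type monotone along each cell's own frames, and across divisions
    last_rank: dict[str, int] = {}
    for _, frame in df.groupby("time_h", sort=True):
        for row in frame.itertuples(index=False):
            rank = _TYPE_RANK[row.cell_type]
            prev = last_rank.get(row.cell_id)
            if prev is None and row.parent_id:
                prev = last_rank.get(row.parent_id)
            if prev is not None and rank < prev:
                raise IntegrityError(
                    f"cell_type of {row.cell_id} moved backward along its lineage"
                )
            last_rank[row.cell_id] = rank


def _check_constant_step(times: np.ndarray) -> float:
    times = np.sort(np.unique(times))
    if len(times) < 2:
        return 0.0
    steps = np.diff(times)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
        raise SamplingError("frame times are not on a constant-step grid")
    return float(steps[0])


# ---------------------------------------------------------------------------
# IO

def read_traces(path: str | Path, schema: str = "traces_csv") -> list[FilamentSeries]:
    """Read a traces CSV into one :class:`FilamentSeries` per filament.

    Parameters
    ----------
    path
        CSV file with exactly the columns of :data:`TRACES_COLUMNS`.
    schema
        Format name; only ``"traces_csv"`` is defined.

    Raises
    ------
    SchemaError
        Missing/extra columns or unknown schema name.
    SamplingError
        Non-constant time step.
    IntegrityError
        Duplicate (cell_id, time), position gaps, type regressions.
    """
    if schema != "traces_csv":
        raise SchemaError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={"filament_id": str, "cell_id": str, "parent_id": str, "cell_type": str},
        keep_default_na=False,
    )
    if list(df.columns) != TRACES_COLUMNS:
        missing = set(TRACES_COLUMNS) - set(df.columns)
        extra = set(df.columns) - set(TRACES_COLUMNS)
        raise SchemaError(f"column mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}")
    df["parent_id"] = df["parent_id"].replace("", None)
    df = df.astype({"time_h": float, "pos_index": int, "gfp": float, "af": float, "area": float})
    _check_constant_step(df["time_h"].to_numpy())
    out = []
    for fid, sub in df.groupby("filament_id", sort=True):
        dup = sub.duplicated(subset=["cell_id", "time_h"])
        if dup.any():
            raise IntegrityError(f"duplicate (cell_id, time) in filament {fid}")
        out.append(FilamentSeries(str(fid), sub.reset_index(drop=True)))
    return out


def write_traces(series: Iterable[FilamentSeries], path: str | Path) -> Path:
    """Write filament series to the traces CSV schema (lossless round trip).

    An empty iterable yields a header-only file; ``parent_id=None`` is
    serialized as an empty field.
    """
    path = Path(path)
    frames = [s.frames for s in series]
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(["filament_id", "time_h", "pos_index"]).reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=TRACES_COLUMNS)
    df = df[TRACES_COLUMNS].copy()
    df["parent_id"] = df["parent_id"].fillna("")
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# vegetative intervals

def intervals_at(series: FilamentSeries, time: float) -> list[VegInterval]:
    """Decompose the frame at ``time`` into vegetative intervals.

    Maximal runs of non-heterocyst cells, each bounded by heterocysts or
    filament ends.  Every vegetative (or differentiating) cell belongs to
    exactly one interval; an all-heterocyst frame yields an empty list.
    """
    frame = series.at(time)
    cells = list(frame.itertuples(index=False))
    intervals: list[VegInterval] = []
    run: list[str] = []
    left: str = FILAMENT_END
    k = 0
    for row in cells:
        if row.cell_type == "heterocyst":
            if run:
                intervals.append(VegInterval(
                    interval_id=f"{series.filament_id}:{k}",
                    filament_id=series.filament_id,
                    time=float(time),
                    cell_ids=run,
                    bounding=(left, row.cell_id),
                ))
                k += 1
                run = []
            left = row.cell_id
        else:
            run.append(row.cell_id)
    if run:
        intervals.append(VegInterval(
            interval_id=f"{series.filament_id}:{k}",
            filament_id=series.filament_id,
            time=float(time),
            cell_ids=run,
            bounding=(left, FILAMENT_END),
        ))
    return intervals


def _interval_membership(series: FilamentSeries, time: float) -> dict[str, tuple[str, float]]:
    """Map cell_id -> (interval_id, distance to nearest bounding heterocyst)."""
    out: dict[str, tuple[str, float]] = {}
    for iv in intervals_at(series, time):
        n = len(iv)
        for i, cid in enumerate(iv.cell_ids):
            d_left = i + 1 if iv.bounding[0] != FILAMENT_END else np.inf
            d_right = n - i if iv.bounding[1] != FILAMENT_END else np.inf
            d = min(d_left, d_right)
            out[cid] = (iv.interval_id, float(d) if np.isfinite(d) else np.nan)
    return out


# ---------------------------------------------------------------------------
# lineage resolution

_POLICIES = ("concentration", "first_daughter", "sum")


def resolve_lineages(series: FilamentSeries, division_policy: str = "concentration") -> list[CellTrace]:
    """Splice per-frame records into one trace per founder-cell lineage.

    Policies
    --------
    ``concentration`` (default)
        Intensities are divided by cell area before splicing, so a division
        (which halves total fluorescence) causes no jump beyond partitioning
        plus measurement noise.  The lineage follows the daughter with the
        smaller position index.
    ``first_daughter``
        Raw total intensities, following the smaller-``pos_index`` daughter.
    ``sum``
        Raw total intensities summed over *all* live descendants of the
        founder at each frame.

    Raises
    ------
    LineageError
        A cell appears after the first frame without an observed parent.
    """
    if division_policy not in _POLICIES:
        raise ValueError(f"unknown division_policy {division_policy!r}; choose from {_POLICIES}")

    times = series.times
    frames = {float(t): series.at(t) for t in times}
    membership = {float(t): _interval_membership(series, t) for t in times}

    # index rows and children per frame
    rows_at: list[dict[str, pd.Series]] = []
    children_at: list[dict[str, list[pd.Series]]] = []
    for t in times:
        frame = frames[float(t)]
        rows = {r.cell_id: r for r in frame.itertuples(index=False)}
        rows_at.append(rows)
        ch: dict[str, list] = {}
        for r in frame.itertuples(index=False):
            if r.parent_id:
                ch.setdefault(r.parent_id, []).append(r)
        children_at.append(ch)

    seen: set[str] = set(rows_at[0])
    for k in range(1, len(times)):
        for cid, r in rows_at[k].items():
            if cid in seen:
                continue
            if not r.parent_id or r.parent_id not in seen:
                raise LineageError(f"orphan cell {cid} at t={times[k]}: parent never observed")
            seen.add(cid)

    def value(r, channel: str) -> float:
        v = getattr(r, channel)
        return v / r.area if division_policy == "concentration" else v

    traces: list[CellTrace] = []
    for root_id, root_row in rows_at[0].items():
        current: list = [root_row]  # live representatives of this lineage
        g, a, iv, dist, ctype = [], [], [], [], []
        for k, t in enumerate(times):
            if k > 0:
                nxt = []
                for r in current:
                    if r.cell_id in rows_at[k]:
                        nxt.append(rows_at[k][r.cell_id])
                    else:
                        kids = sorted(children_at[k].get(r.cell_id, []), key=lambda x: x.pos_index)
                        if not kids:
                            nxt = []
                            break
                        if division_policy == "sum":
                            nxt.extend(kids)
                        else:
                            nxt.append(kids[0])
                if not nxt:
                    break
                current = nxt
            lead = current[0]
            if division_policy == "sum":
                g.append(sum(getattr(r, "gfp") for r in current))
                a.append(sum(getattr(r, "af") for r in current))
            else:
                g.append(value(lead, "gfp"))
                a.append(value(lead, "af"))
            mem = membership[float(t)].get(lead.cell_id)
            if mem is None:  # heterocyst: not in any interval
                iv.append("")
                dist.append(0.0)
            else:
                iv.append(mem[0])
                dist.append(mem[1])
            ctype.append(lead.cell_type)
        n = len(g)
        traces.append(CellTrace(
            cell_id=root_id,
            times=np.asarray(times[:n], dtype=float),
            gfp=np.asarray(g, dtype=float),
            af=np.asarray(a, dtype=float),
            interval_id_per_frame=np.asarray(iv, dtype=object),
            distance_to_heterocyst_per_frame=np.asarray(dist, dtype=float),
            cell_type_per_frame=np.asarray(ctype, dtype=object),
            filament_id=series.filament_id,
        ))
    traces.sort(key=lambda tr: tr.cell_id)
    return traces
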