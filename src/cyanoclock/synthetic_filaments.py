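"""Synthetic filament cohorts with known circadian and differentiation structure.

The generator emulates the statistical regime of nitrogen-deprived *Anabaena*
filaments observed by time-lapse microscopy: filaments are chains of 10–15-cell
vegetative intervals bounded by single heterocysts; every cell expresses a
clock-controlled reporter as a noisy oscillation with period ≈ 21 h sampled
every 30 min; cells within one vegetative interval share a common clock phase
(up to a small per-cell jitter) while different intervals carry independent
phases; heterocysts oscillate with ~5-fold smaller amplitude, inheriting the
phase of their progenitor; photosynthetic-pigment autofluorescence (AF) is flat
in vegetative cells and, in a cell committing to differentiation, starts a
parabolic decay at an onset time whose clock phase is drawn from a narrow
gate; and in the "rise-hold-decay" waveform the per-cycle expression turnoff
is delayed in proportion to the cell's distance from the bounding heterocysts.

Every stochastic choice is logged to a :class:`GroundTruth` table so that the
analysis modules can be tested as parameter-recovery problems.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .trace_model import FilamentSeries, TRACES_COLUMNS

__all__ = [
    "OscillatorParams",
    "DifferentiationParams",
    "NoiseParams",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "regime_preset",
    "load_config",
    "save_config",
]

#: Hours from AF-decay onset to morphological heterocyst commitment.
MATURATION_H = 12.0
#: AF decay is clipped at this fraction of the pre-onset level.
AF_FLOOR_FRAC = 0.05
#: Default segmented cell area, µm².
CELL_AREA_UM2 = 4.0


@dataclass
class OscillatorParams:
    """Parameters of the per-cell circadian expression oscillator.

    ``amplitude_het_ratio`` is the factor by which heterocyst oscillation
    amplitude is *smaller* than the vegetative amplitude (≈5 in nitrogen-
    deprived filaments).  ``within_interval_phase_sd`` is the per-cell phase
    jitter (radians) around the shared interval phase.  In the
    ``rise_hold_decay`` waveform the decay segment of each cycle is delayed by
    ``turnoff_delay_per_cell`` hours per cell of distance to the nearest
    bounding heterocyst.
    """

    period_mean: float = 21.0          # h; 21.3 (heterocysts) vs 20.8 (vegetative) observed
    period_sd: float = 1.0             # h, across cells
    amplitude_veg: float = 500.0       # a.u.
    amplitude_het_ratio: float = 5.0   # veg amplitude / heterocyst amplitude
    baseline: float = 1000.0           # a.u.
    within_interval_phase_sd: float = 0.25   # rad
    across_interval_phase_mode: str = "independent_uniform"  # or "shared"
    turnoff_delay_per_cell: float = 0.5      # h per cell of distance to heterocyst
    waveform: str = "cosine"                 # or "rise_hold_decay"

    def __post_init__(self) -> None:
        if self.period_mean <= 0:
            raise ValueError("period_mean must be positive")
        if self.amplitude_het_ratio < 1:
            raise ValueError("amplitude_het_ratio must be >= 1")
        if self.period_sd < 0 or self.within_interval_phase_sd < 0:
            raise ValueError("sd parameters must be >= 0")
        if self.across_interval_phase_mode not in ("independent_uniform", "shared"):
            raise ValueError(f"unknown phase mode {self.across_interval_phase_mode!r}")
        if self.waveform not in ("cosine", "rise_hold_decay"):
            raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass
class DifferentiationParams:
    """Clock gating and AF-decay parameters of heterocyst differentiation."""

    gate_center: float = 0.6           # phase fraction in [0, 1)
    gate_sd: float = 0.05              # phase fraction
    events_per_interval_per_cycle: float = 0.15
    af_decay_curvature: float = 15.0   # a.u. / h^2 (AF halves in ~6 h at baseline 1000)
    af_baseline_veg: float = 1000.0    # a.u.
    suppression_radius: int = 1        # cells; no event this close to a heterocyst

    def __post_init__(self) -> None:
        if not 0 <= self.gate_center < 1:
            raise ValueError("gate_center must lie in [0, 1)")
        if not 0 <= self.events_per_interval_per_cycle <= 1:
            raise ValueError("events_per_interval_per_cycle must be a probability")


@dataclass
class NoiseParams:
    """Multiplicative noise: per-frame measurement CV and static per-cell CV."""

    measurement_cv: float = 0.05
    extrinsic_cell_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.measurement_cv < 0 or self.extrinsic_cell_cv < 0:
            raise ValueError("noise CVs must be >= 0")


@dataclass
class SimulationConfig:
    """Complete description of one simulated cohort."""

    n_filaments: int = 3
    interval_length_range: tuple[int, int] = (10, 15)
    n_intervals_per_filament: int = 4
    duration_h: float = 96.0
    dt_h: float = 0.5
    oscillator: OscillatorParams = field(default_factory=OscillatorParams)
    differentiation: DifferentiationParams = field(default_factory=DifferentiationParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    division_enabled: bool = False
    doubling_time_h: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.oscillator, dict):
            self.oscillator = OscillatorParams(**self.oscillator)
        if isinstance(self.differentiation, dict):
            self.differentiation = DifferentiationParams(**self.differentiation)
        if isinstance(self.noise, dict):
            self.noise = NoiseParams(**self.noise)
        self.interval_length_range = tuple(int(x) for x in self.interval_length_range)
        if self.dt_h <= 0:
            raise ValueError("dt_h must be positive")
        if self.duration_h < 2 * self.oscillator.period_mean:
            raise ValueError("duration_h must cover at least two oscillation periods")
        lo, hi = self.interval_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid interval_length_range")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["interval_length_range"] = list(self.interval_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown SimulationConfig keys: {unknown}")
        return cls(**d)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML or JSON by file extension."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


@dataclass
class GroundTruth:
    """Per-cell, per-interval, and per-event truth tables for recovery tests."""

    cells: pd.DataFrame       # cell_id, filament_id, interval_id, period_h, phase_rad, extrinsic, distance_to_het, initial_type
    intervals: pd.DataFrame   # interval_id, filament_id, phase_rad, length
    events: pd.DataFrame      # cell_id, interval_id, filament_id, t_on_h, gate_phase, cycle_index
    divisions: pd.DataFrame   # mother_id, daughter_a, daughter_b, time_h
    warnings: list[str] = field(default_factory=list)

    def write_csv(self, out_dir: str | Path, prefix: str = "ground_truth") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name in ("cells", "intervals", "events", "divisions"):
            p = out_dir / f"{prefix}_{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths.append(p)
        return paths


def regime_preset(name: str) -> SimulationConfig:
    """Named study regimes.

    ``nitrogen_replete``: one shared clock phase per filament, no
    differentiation (whole-filament synchrony).  ``nitrogen_deprived``:
    independent uniform phase per vegetative interval, differentiation
    enabled (synchrony confined to intervals).
    """
    if name == "nitrogen_replete":
        return SimulationConfig(
            n_filaments=3,
            n_intervals_per_filament=8,
            oscillator=OscillatorParams(across_interval_phase_mode="shared"),
            differentiation=DifferentiationParams(events_per_interval_per_cycle=0.0),
        )
    if name == "nitrogen_deprived":
        return SimulationConfig(
            n_filaments=3,
            n_intervals_per_filament=8,
            oscillator=OscillatorParams(across_interval_phase_mode="independent_uniform"),
            differentiation=DifferentiationParams(events_per_interval_per_cycle=0.15),
        )
    raise ValueError(f"unknown regime preset {name!r}")


# ---------------------------------------------------------------------------
# simulation internals

def _child_seed(root_seed: int, index: int) -> int:
    # fixed arithmetic so any filament can be regenerated in isolation
    return int((root_seed * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def _waveform(u: np.ndarray, waveform: str, delay_frac: float = 0.0) -> np.ndarray:
    """Unit-amplitude cycle shape vs cycle fraction ``u`` (0 at the minimum).

    ``cosine``: −cos(2πu).  ``rise_hold_decay``: linear rise over 30% of the
    cycle, hold at the peak, then a parabolic decay of fixed 35% duration
    whose *start* is pushed later by ``delay_frac`` of the cycle (capped at
    0.2), followed by a floor at the trough.  The decay keeps its shape as it
    is delayed — cells far from a heterocyst turn off later, not faster.
    """
    if waveform == "cosine":
        return -np.cos(2 * np.pi * u)
    d = min(delay_frac, 0.2)
    w = np.empty_like(u)
    rise = u < 0.3
    hold = (u >= 0.3) & (u < 0.45 + d)
    decay = (u >= 0.45 + d) & (u < 0.8 + d)
    floor = u >= 0.8 + d
    w[rise] = -1.0 + u[rise] / 0.15
    w[hold] = 1.0
    w[decay] = 1.0 - 2.0 * ((u[decay] - 0.45 - d) / 0.35) ** 2
    w[floor] = -1.0
    return w


def _true_minima(period: float, phase: float, duration: float) -> np.ndarray:
    """Times in [0, duration] where the cell's oscillation is at its minimum.

    The oscillator angle is θ(t) = 2π t / T + φ; the cycle fraction is
    u = (θ/2π) mod 1 with u = 0 at a minimum, so minima sit at
    t = T (m − φ/2π) for integer m.
    """
    m_lo = int(np.ceil(phase / (2 * np.pi)))
    m_hi = int(np.floor(duration / period + phase / (2 * np.pi)))
    m = np.arange(m_lo, m_hi + 1)
    return period * (m - phase / (2 * np.pi))


def simulate_cohort(config: SimulationConfig) -> tuple[list[FilamentSeries], GroundTruth]:
    """Generate a cohort of filament series plus its ground-truth log.

    Identical configs (including ``seed``) give identical outputs.
    """
    osc, dif, noi = config.oscillator, config.differentiation, config.noise
    times = np.round(np.arange(0.0, config.duration_h + 1e-9, config.dt_h), 9)
    n_frames = len(times)

    series_list: list[FilamentSeries] = []
    cells_rows, interval_rows, event_rows, division_rows = [], [], [], []
    warn_log: list[str] = []

    for f in range(config.n_filaments):
        fid = f"F{f}"
        rng = np.random.default_rng(_child_seed(config.seed, f))

        # -- structure: H (V*L H) * n_intervals
        lo, hi = config.interval_length_range
        lengths = rng.integers(lo, hi + 1, size=config.n_intervals_per_filament)
        cell_ids: list[str] = []
        cell_interval: list[str] = []     # "" for heterocysts
        cell_dist: list[float] = []       # cells to nearest bounding heterocyst (0 for het)
        is_het0: list[bool] = []
        k = 0

        def add_cell(het: bool, interval: str, dist: float) -> None:
            nonlocal k
            cell_ids.append(f"{fid}C{k:03d}")
            cell_interval.append(interval)
            cell_dist.append(dist)
            is_het0.append(het)
            k += 1

        add_cell(True, "", 0.0)
        for j, L in enumerate(lengths):
            iv_id = f"{fid}:{j}"
            for i in range(int(L)):
                add_cell(False, iv_id, float(min(i + 1, int(L) - i)))
            add_cell(True, "", 0.0)
        n_cells = len(cell_ids)
        idx_by_interval = {
            f"{fid}:{j}": [i for i in range(n_cells) if cell_interval[i] == f"{fid}:{j}"]
            for j in range(config.n_intervals_per_filament)
        }

        # -- oscillator parameters
        if osc.across_interval_phase_mode == "shared":
            shared_phase = rng.uniform(0, 2 * np.pi)
            interval_phase = {iv: shared_phase for iv in idx_by_interval}
        else:
            interval_phase = {iv: rng.uniform(0, 2 * np.pi) for iv in idx_by_interval}
        # the coherent unit shares one period draw: the vegetative interval
        # under independent phases, the whole filament under the shared
        # (nitrogen-replete) mode; heterocysts get their own draw
        if osc.across_interval_phase_mode == "shared":
            fil_period = max(rng.normal(osc.period_mean, osc.period_sd), 1.0)
            interval_period = {iv: fil_period for iv in idx_by_interval}
        else:
            interval_period = {iv: max(rng.normal(osc.period_mean, osc.period_sd), 1.0)
                               for iv in idx_by_interval}
        het_periods = np.maximum(rng.normal(osc.period_mean, osc.period_sd, n_cells), 1.0)
        periods = np.array([
            interval_period[cell_interval[i]] if not is_het0[i] else het_periods[i]
            for i in range(n_cells)
        ])
        eps = rng.normal(0.0, osc.within_interval_phase_sd, n_cells)
        phases = np.empty(n_cells)
        for i in range(n_cells):
            if is_het0[i]:
                phases[i] = rng.uniform(0, 2 * np.pi)  # boundary heterocysts: own phase
            else:
                phases[i] = interval_phase[cell_interval[i]] + eps[i]
        extrinsic = _lognormal_factor(rng, noi.extrinsic_cell_cv, n_cells)

        for iv, ph in interval_phase.items():
            interval_rows.append({
                "interval_id": iv, "filament_id": fid,
                "phase_rad": float(ph % (2 * np.pi)),
                "length": len(idx_by_interval[iv]),
            })

        # -- differentiation events, gated to the clock phase window
        t_on = np.full(n_cells, np.nan)
        event_cycle = np.zeros(n_cells, dtype=int)
        if dif.events_per_interval_per_cycle > 0:
            for iv, members in idx_by_interval.items():
                taken: set[int] = set()
                for cyc in (2, 3, 4):
                    if rng.random() >= dif.events_per_interval_per_cycle:
                        continue
                    eligible = [
                        m for m in members
                        if cell_dist[m] > dif.suppression_radius
                        and all(abs(m - q) > dif.suppression_radius for q in taken)
                        and m not in taken
                    ]
                    if not eligible:
                        continue
                    cell = eligible[rng.integers(len(eligible))]
                    gate = (rng.normal(dif.gate_center, dif.gate_sd)) % 1.0
                    minima = _true_minima(periods[cell], phases[cell], config.duration_h)
                    if len(minima) <= cyc:
                        continue  # cycle does not fit in the observation span
                    t_event = minima[cyc - 1] + gate * periods[cell]
                    if t_event > config.duration_h - 4 * config.dt_h:
                        continue  # too late to observe the decay
                    t_on[cell] = t_event
                    event_cycle[cell] = cyc
                    taken.add(cell)
                    event_rows.append({
                        "cell_id": cell_ids[cell], "interval_id": iv, "filament_id": fid,
                        "t_on_h": float(t_event), "gate_phase": float(gate),
                        "cycle_index": cyc,
                    })

        # -- trace synthesis (vectorized over cells x frames)
        theta = 2 * np.pi * times[None, :] / periods[:, None] + phases[:, None]
        u = (theta / (2 * np.pi)) % 1.0
        w = np.empty_like(u)
        for i in range(n_cells):
            delay_frac = 0.0
            if osc.waveform == "rise_hold_decay" and not is_het0[i] and np.isfinite(cell_dist[i]):
                delay_frac = osc.turnoff_delay_per_cell * cell_dist[i] / periods[i]
            w[i] = _waveform(u[i], osc.waveform, delay_frac)

        amp = np.full((n_cells, n_frames), osc.amplitude_veg)
        amp_het = osc.amplitude_veg / osc.amplitude_het_ratio
        for i in range(n_cells):
            if is_het0[i]:
                amp[i] = amp_het
            elif np.isfinite(t_on[i]):
                # amplitude ramps down to the heterocyst level during maturation
                frac = np.clip((times - t_on[i]) / MATURATION_H, 0.0, 1.0)
                amp[i] = osc.amplitude_veg * (1 - frac) + amp_het * frac

        meas_g = _lognormal_factor(rng, noi.measurement_cv, (n_cells, n_frames))
        meas_a = _lognormal_factor(rng, noi.measurement_cv, (n_cells, n_frames))
        conc_gfp = np.maximum(osc.baseline + amp * w, 0.0) * extrinsic[:, None] * meas_g

        af_shape = np.full((n_cells, n_frames), dif.af_baseline_veg)
        for i in range(n_cells):
            if is_het0[i]:
                af_shape[i] = dif.af_baseline_veg * AF_FLOOR_FRAC
            elif np.isfinite(t_on[i]):
                dtm = np.maximum(times - t_on[i], 0.0)
                af_shape[i] = np.maximum(
                    dif.af_baseline_veg - dif.af_decay_curvature * dtm**2,
                    dif.af_baseline_veg * AF_FLOOR_FRAC,
                )
        conc_af = af_shape * extrinsic[:, None] * meas_a

        ctype = np.full((n_cells, n_frames), "vegetative", dtype=object)
        for i in range(n_cells):
            if is_het0[i]:
                ctype[i] = "heterocyst"
            elif np.isfinite(t_on[i]):
                ctype[i, times >= t_on[i]] = "differentiating"
                ctype[i, times >= t_on[i] + MATURATION_H] = "heterocyst"

        if config.division_enabled:
            df = _assemble_with_divisions(
                fid, cell_ids, times, conc_gfp, conc_af, ctype, rng,
                config.doubling_time_h, division_rows,
            )
        else:
            area = CELL_AREA_UM2
            df = pd.DataFrame({
                "time_h": np.repeat(times, n_cells),
                "filament_id": fid,
                "cell_id": np.tile(cell_ids, n_frames),
                "parent_id": None,
                "pos_index": np.tile(np.arange(n_cells), n_frames),
                "cell_type": ctype.T.reshape(-1),
                "gfp": (conc_gfp * area).T.reshape(-1),
                "af": (conc_af * area).T.reshape(-1),
                "area": area,
            })
        series_list.append(FilamentSeries(fid, df))

        for i in range(n_cells):
            cells_rows.append({
                "cell_id": cell_ids[i], "filament_id": fid,
                "interval_id": cell_interval[i],
                "period_h": float(periods[i]),
                "phase_rad": float(phases[i] % (2 * np.pi)),
                "extrinsic": float(extrinsic[i]),
                "distance_to_het": cell_dist[i],
                "initial_type": "heterocyst" if is_het0[i] else "vegetative",
            })

    truth = GroundTruth(
        cells=pd.DataFrame(cells_rows),
        intervals=pd.DataFrame(interval_rows),
        events=pd.DataFrame(event_rows, columns=[
            "cell_id", "interval_id", "filament_id", "t_on_h", "gate_phase", "cycle_index",
        ]),
        divisions=pd.DataFrame(division_rows, columns=[
            "mother_id", "daughter_a", "daughter_b", "time_h",
        ]),
        warnings=warn_log,
    )
    return series_list, truth


def _assemble_with_divisions(
    fid: str,
    cell_ids: list[str],
    times: np.ndarray,
    conc_gfp: np.ndarray,
    conc_af: np.ndarray,
    ctype: np.ndarray,
    rng: np.random.Generator,
    doubling_time_h: float,
    division_rows: list,
) -> pd.DataFrame:
    """Long table with stochastic binary fissions layered on the concentration signal.

    Each live cell carries the oscillator of its founder (index into the
    concentration matrices).  Lifetimes are Normal(doubling_time, 10%); at
    division the area halves and the would-be total intensity of the mother is
    split binomially (p = 0.5) between the daughters for that frame, mimicking
    partitioning noise.  Heterocysts do not divide.
    """
    n_cells = len(cell_ids)
    next_id = n_cells
    dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
    growth = 2.0 ** (dt / doubling_time_h)

    def draw_lifetime() -> float:
        return max(rng.normal(doubling_time_h, 0.1 * doubling_time_h), 2.0)

    # live: list of dicts in filament order; "osc" indexes the founder oscillator
    live = [
        {"cell_id": cell_ids[i], "osc": i, "parent": None,
         "area": CELL_AREA_UM2, "t_div": draw_lifetime(), "just_born": False}
        for i in range(n_cells)
    ]
    rows: list[dict] = []
    for kf, t in enumerate(times):
        new_live = []
        for cell in live:
            if ctype[cell["osc"], kf] == "vegetative" and t >= cell["t_div"]:
                a_id, b_id = f"{fid}C{next_id:03d}", f"{fid}C{next_id + 1:03d}"
                next_id += 2
                division_rows.append({
                    "mother_id": cell["cell_id"], "daughter_a": a_id,
                    "daughter_b": b_id, "time_h": float(t),
                })
                half = cell["area"] / 2.0
                for d_id in (a_id, b_id):
                    new_live.append({
                        "cell_id": d_id, "osc": cell["osc"], "parent": cell["cell_id"],
                        "area": half, "t_div": t + draw_lifetime(), "just_born": True,
                    })
            else:
                new_live.append(cell)
        live = new_live
        # binomial partitioning of the mother's total intensity at the birth frame
        by_mother: dict[str, list] = {}
        for cell in live:
            if cell["just_born"]:
                by_mother.setdefault(cell["parent"], []).append(cell)
        for sibs in by_mother.values():
            i = sibs[0]["osc"]
            mother_area = sum(c["area"] for c in sibs)
            mg = conc_gfp[i, kf] * mother_area
            ma = conc_af[i, kf] * mother_area
            ga = float(rng.binomial(max(int(round(mg)), 1), 0.5))
            aa = float(rng.binomial(max(int(round(ma)), 1), 0.5))
            sibs[0]["_tg"], sibs[0]["_ta"] = ga, aa
            sibs[1]["_tg"], sibs[1]["_ta"] = mg - ga, ma - aa
        for pos, cell in enumerate(live):
            i = cell["osc"]
            if cell["just_born"]:
                total_g, total_a = cell.pop("_tg"), cell.pop("_ta")
            else:
                total_g = conc_gfp[i, kf] * cell["area"]
                total_a = conc_af[i, kf] * cell["area"]
            rows.append({
                "time_h": float(t), "filament_id": fid, "cell_id": cell["cell_id"],
                "parent_id": cell["parent"], "pos_index": pos,
                "cell_type": ctype[cell["osc"], kf],
                "gfp": total_g, "af": total_a, "area": cell["area"],
            })
        for cell in live:
            cell["just_born"] = False
            cell["area"] *= growth
    return pd.DataFrame(rows)
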