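"""Data model: CSV schema, invariants, lineage splicing, interval resolution."""

import numpy as np
import pandas as pd
import pytest

import cyanoclock as cc
from cyanoclock.trace_model import (
    FILAMENT_END,
    IntegrityError,
    LineageError,
    SamplingError,
    SchemaError,
    intervals_at,
    read_traces,
    resolve_lineages,
    write_traces,
)
from conftest import make_series


class TestReadWrite:
    def test_well_formed_csv_parses(self, two_cell_series, tmp_path):
        p = write_traces([two_cell_series], tmp_path / "t.csv")
        series = read_traces(p)
        assert len(series) == 1
        assert series[0].n_records() == 6
        assert series[0].dt == 0.5

    def test_missing_column_is_schema_error(self, two_cell_series, tmp_path):
        p = write_traces([two_cell_series], tmp_path / "t.csv")
        df = pd.read_csv(p).drop(columns=["area"])
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError):
            read_traces(p)

    def test_non_constant_step_is_sampling_error(self, tmp_path):
        s = make_series([
            {"time_h": t, "cell_id": "c0"} for t in (0.0, 0.5, 1.5)
        ])
        p = write_traces([s], tmp_path / "t.csv")
        with pytest.raises(SamplingError):
            read_traces(p)

    def test_pos_index_gap_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            make_series([
                {"time_h": 0.0, "cell_id": "c0", "pos_index": 0},
                {"time_h": 0.0, "cell_id": "c1", "pos_index": 2},
            ])

    def test_duplicate_cell_frame_is_integrity_error(self, tmp_path):
        s = make_series([
            {"time_h": 0.0, "cell_id": "c0", "pos_index": 0},
            {"time_h": 0.0, "cell_id": "c1", "pos_index": 1},
        ])
        df = s.frames.copy()
        df.loc[1, "cell_id"] = "c0"
        p = tmp_path / "t.csv"
        df["parent_id"] = ""
        df.to_csv(p, index=False)
        with pytest.raises(IntegrityError):
            read_traces(p)

    def test_type_regression_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            make_series([
                {"time_h": 0.0, "cell_id": "c0", "cell_type": "heterocyst"},
                {"time_h": 0.5, "cell_id": "c0", "cell_type": "vegetative"},
            ])

    def test_empty_series_gives_header_only_file(self, tmp_path):
        p = write_traces([], tmp_path / "t.csv")
        text = p.read_text().strip().splitlines()
        assert len(text) == 1
        assert text[0].split(",") == cc.trace_model.TRACES_COLUMNS

    def test_null_parent_serialized_as_empty_field(self, two_cell_series, tmp_path):
        p = write_traces([two_cell_series], tmp_path / "t.csv")
        first_row = p.read_text().splitlines()[1].split(",")
        assert first_row[3] == ""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_lossless_on_simulated_cohorts(self, seed, tmp_path):
        config = cc.SimulationConfig(n_filaments=2, n_intervals_per_filament=2,
                                     duration_h=48.0, seed=seed)
        series, _ = cc.simulate_cohort(config)
        p = write_traces(series, tmp_path / "t.csv")
        back = read_traces(p)
        assert len(back) == len(series)
        for a, b in zip(series, back):
            pd.testing.assert_frame_equal(a.frames, b.frames)


class TestIntervals:
    def test_bounded_interval(self, patterned_series):
        ivs = intervals_at(patterned_series, 0.0)
        assert len(ivs) == 1
        assert ivs[0].cell_ids == ["c1", "c2", "c3"]
        assert not ivs[0].end_bounded
        assert ivs[0].bounding == ("c0", "c4")

    def test_end_bounded_intervals(self):
        types = ["vegetative", "vegetative", "heterocyst", "vegetative", "vegetative"]
        s = make_series([{"time_h": 0.0, "cell_id": f"c{i}", "pos_index": i,
                          "cell_type": ct} for i, ct in enumerate(types)])
        ivs = intervals_at(s, 0.0)
        assert [len(iv) for iv in ivs] == [2, 2]
        assert all(iv.end_bounded for iv in ivs)
        assert ivs[0].bounding == (FILAMENT_END, "c2")

    def test_intervals_partition_vegetative_cells(self):
        config = cc.SimulationConfig(n_filaments=1, n_intervals_per_filament=3,
                                     duration_h=48.0, seed=7)
        series, truth = cc.simulate_cohort(config)
        s = series[0]
        for t in (0.0, 24.0, 47.5):
            frame = s.at(t)
            veg = set(frame.loc[frame["cell_type"] != "heterocyst", "cell_id"])
            covered = [c for iv in intervals_at(s, t) for c in iv.cell_ids]
            assert sorted(covered) == sorted(veg)
            assert len(covered) == len(set(covered))

    def test_interval_lengths_match_ground_truth(self):
        config = cc.SimulationConfig(n_filaments=1, n_intervals_per_filament=4,
                                     duration_h=48.0, seed=3,
                                     differentiation=cc.DifferentiationParams(
                                         events_per_interval_per_cycle=0.0))
        series, truth = cc.simulate_cohort(config)
        ivs = [iv for iv in intervals_at(series[0], 0.0) if not iv.end_bounded]
        assert [len(iv) for iv in ivs] == list(truth.intervals["length"])


class TestLineages:
    def test_no_divisions_identity(self, two_cell_series):
        traces = resolve_lineages(two_cell_series, "first_daughter")
        assert len(traces) == 2
        tr = {t.cell_id: t for t in traces}["c0"]
        assert np.allclose(tr.gfp, [100.0, 110.0, 120.0])

    def test_first_daughter_follows_lower_pos_index(self, division_series):
        traces = resolve_lineages(division_series, "first_daughter")
        assert len(traces) == 1
        tr = traces[0]
        assert len(tr.times) == 3
        assert np.allclose(tr.gfp, [200.0, 98.0, 99.0])

    def test_sum_policy_adds_daughters(self, division_series):
        tr = resolve_lineages(division_series, "sum")[0]
        assert np.allclose(tr.gfp, [200.0, 200.0, 202.0])

    def test_concentration_policy_divides_by_area(self, division_series):
        tr = resolve_lineages(division_series, "concentration")[0]
        assert np.allclose(tr.gfp, [200.0 / 8, 98.0 / 4, 99.0 / 4])

    def test_orphan_cell_raises(self):
        with pytest.raises(LineageError):
            resolve_lineages(make_series([
                {"time_h": 0.0, "cell_id": "c0"},
                {"time_h": 0.5, "cell_id": "c0"},
                {"time_h": 0.5, "cell_id": "ghost", "parent_id": "unknown",
                 "pos_index": 1},
            ]))

    def test_trace_count_equals_root_count_with_divisions(self):
        config = cc.SimulationConfig(
            n_filaments=1, n_intervals_per_filament=2, duration_h=48.0,
            division_enabled=True, seed=4,
            differentiation=cc.DifferentiationParams(events_per_interval_per_cycle=0.0))
        series, truth = cc.simulate_cohort(config)
        assert len(truth.divisions) > 0
        traces = resolve_lineages(series[0], "concentration")
        assert len(traces) == len(series[0].at(0.0))

    def test_concentration_jumps_bounded_at_divisions(self):
        """Relative concentration jump at division stays within 5x the
        measurement CV for at least 99% of divisions."""
        jumps = []
        for seed in range(4):
            config = cc.SimulationConfig(
                n_filaments=1, n_intervals_per_filament=3, duration_h=72.0,
                division_enabled=True, seed=seed,
                differentiation=cc.DifferentiationParams(events_per_interval_per_cycle=0.0))
            series, truth = cc.simulate_cohort(config)
            traces = resolve_lineages(series[0], "concentration")
            div_times = set(truth.divisions["time_h"])
            for tr in traces:
                for k, t in enumerate(tr.times[1:], start=1):
                    if t in div_times:
                        jumps.append(abs(tr.gfp[k] - tr.gfp[k - 1]) / tr.gfp[k - 1])
        jumps = np.asarray(jumps)
        assert len(jumps) > 50
        cv = cc.NoiseParams().measurement_cv
        assert (jumps <= 5 * cv).mean() >= 0.99
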