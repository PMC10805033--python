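"""Minima/period/amplitude estimation, event alignment, turnoff gradients."""

import numpy as np
import pytest

import cyanoclock as cc
from cyanoclock.oscillation_features import (
    CycleWindow,
    FeatureError,
    GradientError,
    NoTurnoffError,
    TurnoffRecord,
    align_by_event,
    amplitude,
    amplitude_ratio,
    cycle_windows,
    detect_minima,
    detect_turnoff,
    estimate_period,
    mean_turnoff_gradient,
    turnoff_gradient,
)
from cyanoclock.trace_model import resolve_lineages


def cosine(t, period=21.0, phase=0.0, baseline=1000.0, amp=500.0):
    return baseline + amp * np.cos(2 * np.pi * t / period + phase)


class TestDetectMinima:
    def test_pure_cosine_recovered_within_one_frame(self):
        t = np.arange(0, 42.01, 0.5)
        mins = [m.time for m in detect_minima(t, cosine(t), 21.0)]
        assert len(mins) == 2
        assert abs(mins[0] - 10.5) <= 0.5
        assert abs(mins[1] - 31.5) <= 0.5

    def test_monotone_ramp_gives_empty_list(self):
        t = np.arange(0, 42.01, 0.5)
        assert detect_minima(t, 2.0 * t + 3.0, 21.0) == []

    def test_short_trace_rejected(self):
        t = np.arange(0, 10.0, 0.5)
        with pytest.raises(FeatureError):
            detect_minima(t, cosine(t), 21.0)

    def test_time_shift_equivariance(self):
        t = np.arange(0, 63.01, 0.5)
        y = cosine(t, phase=0.7)
        base = [m.time for m in detect_minima(t, y, 21.0)]
        shifted = [m.time for m in detect_minima(t + 4.0, y, 21.0)]
        np.testing.assert_allclose(np.array(shifted) - 4.0, base, atol=1e-9)

    def test_constant_offset_invariance(self):
        t = np.arange(0, 63.01, 0.5)
        y = cosine(t, phase=1.3)
        base = [m.time for m in detect_minima(t, y, 21.0)]
        offset = [m.time for m in detect_minima(t, y + 250.0, 21.0)]
        np.testing.assert_allclose(offset, base, atol=1e-9)

    def test_noisy_minima_within_stated_precision(self):
        """At 5% measurement noise, at least 95% of minima land within 1 h of
        truth (500 replicates)."""
        rng = np.random.default_rng(0)
        t = np.arange(0, 63.01, 0.5)
        errors = []
        for _ in range(500):
            phase = rng.uniform(0, 2 * np.pi)
            y = cosine(t, phase=phase) * rng.lognormal(
                -np.log1p(0.05**2) / 2, np.sqrt(np.log1p(0.05**2)), len(t))
            true = 21.0 * ((np.pi - phase) / (2 * np.pi) + np.arange(-1, 5))
            true = true[(true >= 0) & (true <= 63.0)]
            for m in detect_minima(t, y, 21.0):
                errors.append(np.min(np.abs(true - m.time)))
        errors = np.asarray(errors)
        assert (errors <= 1.0).mean() >= 0.95


class TestPeriodAndWindows:
    def test_single_trace_exact(self):
        assert estimate_period([0.0, 21.0, 42.0]) == (21.0, 0.0)

    def test_single_trace_uneven(self):
        mean, se = estimate_period([0.0, 20.0, 42.0])
        assert mean == pytest.approx(21.0)

    def test_cohort_se_over_traces(self):
        mean, se = estimate_period([[0, 20, 40], [0, 22, 44]])
        assert mean == pytest.approx(21.0)
        assert se == pytest.approx(np.std([20, 22], ddof=1) / np.sqrt(2))

    def test_rescaling_invariance(self):
        t = np.arange(0, 63.01, 0.5)
        y = cosine(t, phase=0.4)
        m1 = estimate_period([m.time for m in detect_minima(t, y, 21.0)])
        m2 = estimate_period([m.time for m in detect_minima(t, 7.0 * y, 21.0)])
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_cycle_windows_tile_span(self):
        wins = cycle_windows([0.0, 21.0, 42.0])
        assert [(w.t_start, w.t_end, w.cycle_index) for w in wins] == [
            (0.0, 21.0, 1), (21.0, 42.0, 2)]
        assert cycle_windows([10.0]) == []


class TestAmplitude:
    def test_cosine_amplitude(self):
        t = np.arange(0, 42.01, 0.5)
        a = amplitude(t, cosine(t, amp=300.0), CycleWindow(0.0, 21.0, 1))
        assert a == pytest.approx(300.0, rel=0.02)

    def test_constant_trace_amplitude_zero(self):
        t = np.arange(0, 42.01, 0.5)
        assert amplitude(t, np.full_like(t, 7.0), CycleWindow(0.0, 21.0, 1)) == 0.0

    def test_generator_ratio_recovered_noiselessly(self):
        config = cc.SimulationConfig(
            n_filaments=2, n_intervals_per_filament=3, seed=5,
            noise=cc.NoiseParams(measurement_cv=0.0, extrinsic_cell_cv=0.0),
            differentiation=cc.DifferentiationParams(events_per_interval_per_cycle=0.0))
        series, _ = cc.simulate_cohort(config)
        veg, het = [], []
        for s in series:
            for tr in resolve_lineages(s):
                pair = (tr.times, tr.gfp)
                (het if tr.cell_type_per_frame[0] == "heterocyst" else veg).append(pair)
        assert amplitude_ratio(veg, het) == pytest.approx(5.0, rel=0.05)


class TestAlignByEvent:
    def test_two_identical_traces_shifted(self):
        t = np.arange(0, 10.0, 0.5)
        y = np.sin(t)
        rel, mat, mean = align_by_event([(t, y), (t + 2.0, y)], [3.0, 5.0])
        present = ~np.isnan(mat).any(axis=0)
        np.testing.assert_allclose(mat[0, present], mat[1, present])
        np.testing.assert_allclose(mean[present], mat[0, present])

    def test_phase_aligned_cosines_preserve_amplitude(self):
        """Averaging event-aligned noiseless cosines loses no amplitude when
        the events mark a common phase."""
        period = 21.0
        t = np.arange(0, 63.0, 0.5)
        traces, events = [], []
        for phase in (0.0, 1.0, 2.0, 3.0):
            traces.append((t, np.cos(2 * np.pi * t / period - phase)))
            events.append(phase * period / (2 * np.pi))  # time of cos max
        rel, mat, mean = align_by_event(traces, events)
        full = ~np.isnan(mat).any(axis=0)
        # events are snapped to the nearest frame, so the residual smear is
        # below half a frame: amplitude loss stays under 1%
        assert np.nanmax(mean[full]) == pytest.approx(1.0, abs=0.01)

    def test_single_trace_mean_is_trace(self):
        t = np.arange(0, 5.0, 0.5)
        y = t**2
        _, _, mean = align_by_event([(t, y)], [2.0])
        np.testing.assert_allclose(mean, y)

    def test_event_outside_span_rejected(self):
        t = np.arange(0, 5.0, 0.5)
        with pytest.raises(FeatureError):
            align_by_event([(t, t)], [9.0])


class TestTurnoff:
    def test_zero_delay_slope_near_zero(self):
        from cyanoclock.validation import turnoff_recovery_experiment
        slope, n_groups = turnoff_recovery_experiment(seed=0, delay=0.0,
                                                      n_filaments=2, n_intervals=4)
        assert n_groups >= 10
        assert abs(slope) <= 0.1

    def test_single_distance_gradient_rejected(self):
        recs = [TurnoffRecord("a", 1, 10.0, 2.0), TurnoffRecord("b", 1, 11.0, 2.0)]
        with pytest.raises(GradientError):
            turnoff_gradient(recs)

    def test_no_decay_raises(self):
        t = np.arange(0, 21.0, 0.5)
        rising = 10.0 + t
        with pytest.raises(NoTurnoffError):
            detect_turnoff(t, rising, CycleWindow(0.0, 20.5, 1))

    def test_gradient_clusters_drifting_cycle_indices(self):
        # two cycles one period apart, mislabelled with the same cycle index
        recs = [TurnoffRecord("a", 1, 10.0 + 0.5 * d, d, "iv") for d in (1, 2, 3, 4)]
        recs += [TurnoffRecord("b", 1, 31.0 + 0.5 * d, d, "iv") for d in (1, 2, 3, 4)]
        slope, n_groups = mean_turnoff_gradient(recs)
        assert n_groups == 2
        assert slope == pytest.approx(0.5)
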