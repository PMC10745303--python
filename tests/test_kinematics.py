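import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sinusoid_traj
from oracles import drawing_arc_length, per_cycle_geomean_oracle
from tremorvideo import (
    AnalysisConfig,
    TrajectorySeries,
    TremorSpec,
    amplitude_geometric_mean,
    compute_kinematics,
    cumulative_length,
    estimate_frequency,
    generate_drawing_trajectory,
    generate_postural_trajectory,
    log_change,
    select_analysis_window,
    summarize_task,
    tremor_signal,
)


class TestKinematicFormulas:
    def test_three_four_five_displacement_and_velocity(self):
        traj = TrajectorySeries(x=[0.0, 3.0, 6.0], y=[0.0, 4.0, 8.0], fps=25, units="mm")
        kin = compute_kinematics(traj)
        assert kin.displacement[0] == 5.0
        assert kin.velocity[0] == 125.0
        assert kin.acceleration[0] == 0.0

    def test_acceleration_from_velocity_step(self):
        # 100 mm/s then 125 mm/s at 25 fps -> (125-100)/0.04 = 625 mm/s^2
        traj = TrajectorySeries(x=[0.0, 4.0, 9.0], y=[0.0, 0.0, 0.0], fps=25, units="mm")
        kin = compute_kinematics(traj)
        assert kin.velocity.tolist() == [100.0, 125.0]
        assert kin.acceleration[0] == 625.0

    def test_constant_position_all_zero(self):
        traj = TrajectorySeries(x=np.full(10, 3.0), y=np.full(10, -2.0), fps=25, units="mm")
        kin = compute_kinematics(traj)
        assert not kin.displacement.any()
        assert not kin.velocity.any()
        assert not kin.acceleration.any()

    def test_lengths(self):
        traj = TrajectorySeries(x=np.arange(12.0), y=np.zeros(12), fps=25, units="mm")
        kin = compute_kinematics(traj)
        assert len(kin.displacement) == 11
        assert len(kin.velocity) == 11
        assert len(kin.acceleration) == 10

    def test_uncalibrated_pixels_rejected(self):
        traj = TrajectorySeries(x=[0.0, 1.0, 2.0], y=[0.0, 0.0, 0.0], fps=25, units="px")
        with pytest.raises(ValueError, match="calibration"):
            compute_kinematics(traj)


class TestTremorSignal:
    def test_recovers_amplitude_on_oblique_axis(self):
        traj = make_sinusoid_traj(frequency=4.0, half_amplitude=10.0, axis_deg=30.0, duration=20)
        sig = tremor_signal(traj)
        # evaluate away from the recording edges, where the baseline is a
        # local linear fit rather than a full centred moving average
        interior = sig[25:-25]
        assert np.ptp(interior) == pytest.approx(20.0, rel=0.02)

    def test_pure_drift_leaves_no_residual(self):
        n = 501
        t = np.arange(n) / 25.0
        traj = TrajectorySeries(x=5.0 * t, y=-2.0 * t, fps=25, units="mm")
        sig = tremor_signal(traj)
        assert np.sqrt((sig**2).mean()) < 1e-8

    def test_sinusoid_plus_drift_matches_sinusoid(self):
        fps, dur = 25.0, 20.0
        traj = make_sinusoid_traj(
            frequency=5.0, half_amplitude=10.0, fps=fps, duration=dur, drift=3.0
        )
        t = np.arange(traj.n) / fps
        truth = 10.0 * np.sin(2 * np.pi * 5.0 * t)
        sig = tremor_signal(traj)
        rmse = np.sqrt(((sig - truth) ** 2).mean())
        assert rmse < 0.03 * np.sqrt((truth**2).mean()) + 1e-9

    def test_constant_trajectory_gives_zero_signal(self):
        traj = TrajectorySeries(x=np.full(100, 1.0), y=np.full(100, 2.0), fps=25, units="mm")
        assert np.abs(tremor_signal(traj)).max() < 1e-10


class TestWindowRule:
    def _burst_traj(self, t0, width=3.0, freq=5.0, fps=25.0):
        env = lambda t: np.exp(-0.5 * ((t - t0) / width) ** 2)
        return make_sinusoid_traj(
            frequency=freq, half_amplitude=10.0, fps=fps, duration=60.0, envelope=env
        )

    def test_burst_in_interior_centres_window(self):
        w = select_analysis_window(self._burst_traj(30.0))
        assert w.center == pytest.approx(30.0, abs=0.2)
        assert w.end - w.start == pytest.approx(10.0)

    def test_early_burst_clamped_to_search_start(self):
        w = select_analysis_window(self._burst_traj(3.0, width=1.5))
        assert w.start == pytest.approx(0.0)
        assert w.end == pytest.approx(10.0)

    def test_late_burst_clamped_to_search_end(self):
        w = select_analysis_window(self._burst_traj(58.0, width=1.5))
        assert w.center == pytest.approx(55.0)
        assert w.end == pytest.approx(60.0)

    def test_constant_amplitude_ties_break_earliest(self):
        # 5 Hz at 25 fps: every 1 s envelope window sees identical sample sets
        traj = make_sinusoid_traj(frequency=5.0, half_amplitude=10.0, duration=60.0)
        w = select_analysis_window(traj)
        assert w.center == 5.0
        assert (w.start, w.end) == (0.0, 10.0)

    def test_window_has_exact_sample_count(self):
        traj = self._burst_traj(20.0)
        w = select_analysis_window(traj)
        sub = traj.crop(w.start, w.end)
        assert sub.n == 251  # window_length * fps + 1

    def test_short_recording_rejected_with_minimum(self):
        traj = make_sinusoid_traj(duration=30.0)
        with pytest.raises(ValueError, match="60.00"):
            select_analysis_window(traj)

    def test_custom_search_range_for_short_recordings(self):
        traj = make_sinusoid_traj(frequency=5.0, duration=20.0)
        w = select_analysis_window(traj, search_range=(5.0, 15.0))
        assert 0.0 <= w.start and w.end <= 20.0


class TestFrequency:
    @pytest.mark.parametrize("freq", [0.5, 4.0, 9.5])
    def test_pure_sinusoid(self, freq):
        fps = 25.0
        n = 251
        t = np.arange(n) / fps
        sig = 10.0 * np.sin(2 * np.pi * freq * t)
        est, flag = estimate_frequency(sig, fps)
        assert not flag
        assert est == pytest.approx(freq, abs=0.05)

    def test_linear_chirp_counts_mean_frequency(self):
        # 3 -> 5 Hz over 10 s: integrated instantaneous frequency = 40 cycles
        fps = 25.0
        t = np.arange(251) / fps
        phase = 2 * np.pi * (3.0 * t + 0.1 * t**2)  # f(t) = 3 + 0.2 t
        sig = 10.0 * np.sin(phase)
        est, _ = estimate_frequency(sig, fps)
        assert est == pytest.approx(4.0, abs=0.1)

    def test_zero_signal_flags_no_tremor(self):
        est, flag = estimate_frequency(np.zeros(251), 25.0)
        assert est == 0.0
        assert flag


class TestAmplitude:
    def test_constant_sinusoid_peak_to_peak(self):
        t = np.arange(251) / 25.0
        sig = 10.0 * np.sin(2 * np.pi * 4.0 * t)
        amp, ncyc = amplitude_geometric_mean(sig, 25.0)
        assert amp == pytest.approx(20.0, rel=0.01)
        assert ncyc >= 38

    def test_alternating_cycles_geometric_mean(self):
        # per-cycle half-amplitudes alternate 5 and 20 mm -> geomean p2p = 20
        fps, freq = 100.0, 2.0
        t = np.arange(int(10 * fps) + 1) / fps
        cycle_idx = np.floor(freq * t).astype(int)
        half_amp = np.where(cycle_idx % 2 == 0, 5.0, 20.0)
        sig = half_amp * np.sin(2 * np.pi * freq * t)
        amp, _ = amplitude_geometric_mean(sig, fps)
        assert amp == pytest.approx(math.sqrt(10.0 * 40.0), rel=0.02)

    def test_amplitude_modulated_signal_matches_per_cycle_oracle(self):
        fps, freq, dur = 100.0, 4.0, 10.0
        t = np.arange(int(dur * fps) + 1) / fps
        mod = 1.0 + 0.4 * np.sin(2 * np.pi * 0.3 * t)
        sig = 10.0 * mod * np.sin(2 * np.pi * freq * t)
        amp, _ = amplitude_geometric_mean(sig, fps)
        # oracle: half-amplitude of each zero-crossing cycle from the known envelope
        n_cycles = int(freq * dur)
        halves = []
        for k in range(n_cycles):
            tt = np.linspace(k / freq, (k + 1) / freq, 500)
            vals = 10.0 * (1.0 + 0.4 * np.sin(2 * np.pi * 0.3 * tt)) * np.sin(
                2 * np.pi * freq * tt
            )
            halves.append((vals.max() - vals.min()) / 2)
        expected = per_cycle_geomean_oracle(np.array(halves))
        assert amp == pytest.approx(expected, rel=0.03)

    def test_half_amplitude_mode(self):
        t = np.arange(251) / 25.0
        sig = 10.0 * np.sin(2 * np.pi * 4.0 * t)
        amp, _ = amplitude_geometric_mean(sig, 25.0, AnalysisConfig(amplitude_mode="half"))
        assert amp == pytest.approx(10.0, rel=0.01)

    def test_no_cycles_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            amplitude_geometric_mean(np.zeros(251), 25.0)


class TestCumulativeLength:
    def test_closed_square_path(self):
        # 10 mm sides traversed at constant speed
        side = np.linspace(0, 10, 26)
        x = np.concatenate([side, np.full(25, 10.0), side[::-1][1:], np.zeros(25)])
        y = np.concatenate([np.zeros(26), side[1:], np.full(25, 10.0), side[::-1][1:]])
        traj = TrajectorySeries(x=x, y=y, fps=25, units="mm")
        length = cumulative_length(traj, span=(0.0, traj.duration))
        assert length == pytest.approx(40.0, abs=1e-9)

    def test_at_least_net_displacement(self):
        spec = TremorSpec(base_frequency=5.0, peak_to_peak_amplitude=30.0, noise_sd=0.1, seed=3)
        traj = generate_drawing_trajectory(spec, 150.0, 6.0)
        length = cumulative_length(traj, span=(0.0, 6.0))
        net = np.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0])
        assert length >= net

    def test_span_autodetection_matches_known_span(self):
        spec = TremorSpec(peak_to_peak_amplitude=0.0, noise_sd=0.0, seed=0)
        traj = generate_drawing_trajectory(spec, 150.0, 6.0)
        assert cumulative_length(traj) == pytest.approx(150.0, abs=1.0)

    def test_empty_span_raises(self):
        traj = TrajectorySeries(x=np.zeros(100), y=np.zeros(100), fps=25, units="mm")
        with pytest.raises(ValueError, match="span"):
            cumulative_length(traj)

    def test_matches_arc_length_oracle(self):
        spec = TremorSpec(base_frequency=3.0, peak_to_peak_amplitude=40.0, fps=250.0, seed=0)
        traj = generate_drawing_trajectory(spec, 150.0, 6.0)
        expected = drawing_arc_length(150.0, 6.0, half_amplitude=20.0, frequency=3.0)
        assert cumulative_length(traj, span=(0.0, 6.0)) == pytest.approx(expected, rel=0.02)


class TestSummarizeTask:
    def test_postural_recovery_with_mild_noise(self):
        spec = TremorSpec(
            base_frequency=5.0, peak_to_peak_amplitude=30.0, noise_sd=0.05, seed=21
        )
        m = summarize_task(generate_postural_trajectory(spec), "postural")
        assert m.mean_frequency_hz == pytest.approx(5.0, abs=0.1)
        assert m.amplitude_mm == pytest.approx(30.0, abs=1.5)
        assert m.cumulative_length_mm is None
        assert m.window is not None

    def test_zero_amplitude_flags_no_tremor(self):
        spec = TremorSpec(peak_to_peak_amplitude=0.0, noise_sd=0.0, seed=0)
        m = summarize_task(generate_postural_trajectory(spec), "postural")
        assert m.no_tremor
        assert math.isnan(m.amplitude_mm)
        assert m.mean_frequency_hz == 0.0
        assert m.n_cycles == 0

    def test_drawing_without_tremor_recovers_line_length(self):
        spec = TremorSpec(peak_to_peak_amplitude=0.0, noise_sd=0.0, seed=0)
        m = summarize_task(generate_drawing_trajectory(spec, 150.0, 6.0), "drawing")
        assert m.cumulative_length_mm == pytest.approx(150.0, abs=1.0)
        assert m.no_tremor

    def test_drawing_with_tremor_has_all_five_parameters(self):
        spec = TremorSpec(base_frequency=4.0, peak_to_peak_amplitude=20.0, seed=5)
        m = summarize_task(generate_drawing_trajectory(spec, 150.0, 6.0), "drawing")
        assert m.mean_frequency_hz == pytest.approx(4.0, abs=0.15)
        assert m.amplitude_mm == pytest.approx(20.0, rel=0.05)
        assert m.cumulative_length_mm > 150.0
        assert m.mean_velocity_mm_s > 0
        assert m.mean_acceleration_mm_s2 > 0

    def test_invalid_task_name(self):
        traj = make_sinusoid_traj(duration=5)
        with pytest.raises(ValueError, match="task"):
            summarize_task(traj, "resting")


class TestInvariances:
    @pytest.mark.parametrize("angle_deg", [17.0, 90.0, 203.0])
    def test_metrics_invariant_under_rotation_and_translation(self, angle_deg):
        spec = TremorSpec(base_frequency=6.0, peak_to_peak_amplitude=25.0, seed=31)
        traj = generate_postural_trajectory(spec)
        m0 = summarize_task(traj, "postural")
        th = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = traj.xy @ rot.T + np.array([113.0, -77.0])
        traj2 = TrajectorySeries(x=xy[:, 0], y=xy[:, 1], fps=traj.fps, units="mm")
        m1 = summarize_task(traj2, "postural")
        # invariant up to the discrete window tie-break: a constant-amplitude
        # signal has many near-equal envelope maxima, so the selected window
        # (not the physics) may shift by a few samples under rotation
        assert m1.mean_frequency_hz == pytest.approx(m0.mean_frequency_hz, abs=0.05)
        assert m1.amplitude_mm == pytest.approx(m0.amplitude_mm, rel=0.01)
        assert m1.mean_velocity_mm_s == pytest.approx(m0.mean_velocity_mm_s, rel=0.01)

    def test_amplitude_and_length_scale_linearly(self):
        spec = TremorSpec(base_frequency=4.0, peak_to_peak_amplitude=10.0, seed=41)
        traj = generate_drawing_trajectory(spec, 150.0, 6.0)
        m0 = summarize_task(traj, "drawing", span=(0.0, 6.0))
        traj3 = TrajectorySeries(x=3 * traj.x, y=3 * traj.y, fps=traj.fps, units="mm")
        m3 = summarize_task(traj3, "drawing", span=(0.0, 6.0))
        assert m3.amplitude_mm == pytest.approx(3 * m0.amplitude_mm, rel=1e-6)
        assert m3.cumulative_length_mm == pytest.approx(3 * m0.cumulative_length_mm, rel=1e-9)


class TestLogChange:
    def test_reference_values(self):
        assert log_change(10.0, 1.0) == pytest.approx(-1.0)
        assert log_change(7.3, 7.3) == 0.0
        assert log_change(14.0, 2.7) == pytest.approx(math.log10(2.7 / 14.0))
        assert log_change(14.0, 2.7) == pytest.approx(-0.715, abs=5e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_change(0.0, 1.0)
        with pytest.raises(ValueError):
            log_change(1.0, -2.0)

    @given(
        t1=st.floats(1e-6, 1e6, allow_nan=False),
        t2=st.floats(1e-6, 1e6, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_antisymmetry_exact(self, t1, t2):
        assert log_change(t1, t2) == -log_change(t2, t1)
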