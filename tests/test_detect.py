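"""Detector: speed computation, threshold parsing, metrics, invariances."""

import numpy as np
import pytest

from oculostim import (
    EyeTrace,
    SimConfig,
    compute_speed,
    detect_saccades,
    main_sequence_params,
    saccade_metrics,
    simulate_session,
    synth_saccade_segment,
)
from oculostim.detect import SaccadeInterval
from oculostim.errors import InvalidArgumentError
from oculostim.pipeline import build_saccade_table


def _trace_with_saccade(onset_ms=300.0, amp=7.0, total_ms=800.0,
                        noise=0.0, seed=0, rate=500.0, start=(0.0, 0.0),
                        direction=(1.0, 0.0)):
    dt = 1000.0 / rate
    n = int(total_ms / dt)
    t = np.arange(n) * dt
    x = np.full(n, start[0])
    y = np.full(n, start[1])
    end = (start[0] + amp * direction[0], start[1] + amp * direction[1])
    ts, xy = synth_saccade_segment(start, end, onset_ms, rate)
    for k, tk in enumerate(ts):
        i = int(round(tk / dt))
        if i < n:
            x[i], y[i] = xy[k]
    x[int(round(ts[-1] / dt)):] = end[0]
    y[int(round(ts[-1] / dt)):] = end[1]
    if noise > 0:
        rng = np.random.default_rng(seed)
        x = x + noise * rng.standard_normal(n)
        y = y + noise * rng.standard_normal(n)
    return EyeTrace(t, x, y, rate)


class TestComputeSpeed:
    def test_constant_position_has_zero_speed(self):
        t = np.arange(100) * 2.0
        tr = EyeTrace(t, np.full(100, 3.0), np.full(100, -1.0), 500.0)
        assert np.allclose(compute_speed(tr), 0.0)

    def test_linear_ramp_speed_is_exact(self):
        t = np.arange(100) * 2.0
        tr = EyeTrace(t, 0.010 * t, np.zeros(100), 500.0)  # 10 deg/s in x
        assert np.allclose(compute_speed(tr), 10.0)

    def test_peak_speed_of_synthetic_saccade(self):
        _, peak = main_sequence_params(7.0)
        tr = _trace_with_saccade()
        assert np.max(compute_speed(tr)) == pytest.approx(peak, rel=0.03)

    def test_too_few_samples_rejected(self):
        tr = EyeTrace([0.0, 2.0], [0.0, 0.0], [0.0, 0.0], 500.0)
        with pytest.raises(InvalidArgumentError):
            compute_speed(tr)


class TestDetectSaccades:
    def test_fixation_only_noise_yields_no_saccades(self):
        rng = np.random.default_rng(1)
        t = np.arange(500) * 2.0
        tr = EyeTrace(t, 0.05 * rng.standard_normal(500),
                      0.05 * rng.standard_normal(500), 500.0)
        assert detect_saccades(tr) == []

    def test_single_saccade_onset_recovered(self):
        tr = _trace_with_saccade(onset_ms=150.0, noise=0.05, seed=3,
                                 total_ms=600.0)
        intervals = detect_saccades(tr)
        assert len(intervals) == 1
        assert abs(intervals[0].onset_ms - 150.0) <= 4.0

    def test_two_separated_saccades_detected_in_order(self):
        tr1 = _trace_with_saccade(onset_ms=200.0, total_ms=900.0)
        # append a second, return saccade 300 ms later
        ts, xy = synth_saccade_segment((7, 0), (0, 0), 500.0, 500.0)
        x, y = tr1.x_deg.copy(), tr1.y_deg.copy()
        for k, tk in enumerate(ts):
            i = int(round(tk / 2.0))
            x[i], y[i] = xy[k]
        x[int(round(ts[-1] / 2.0)):] = 0.0
        tr = EyeTrace(tr1.t_ms, x, y, 500.0)
        intervals = detect_saccades(tr)
        assert len(intervals) == 2
        assert intervals[0].offset_ms < intervals[1].onset_ms
        assert abs(intervals[0].onset_ms - 200.0) <= 4.0
        assert abs(intervals[1].onset_ms - 500.0) <= 4.0

    def test_nan_inside_candidate_run_excludes_it(self):
        tr = _trace_with_saccade(onset_ms=300.0)
        x = tr.x_deg.copy()
        x[int(round(318 / 2.0))] = np.nan  # mid-flight sample missing
        tr_bad = EyeTrace(tr.t_ms, x, tr.y_deg, 500.0)
        assert detect_saccades(tr_bad) == []

    def test_raising_threshold_never_adds_intervals(self):
        cfg = SimConfig.no_effect(n_electrodes=4, grid_shape=(2, 2))
        session = simulate_session(cfg, seed=13)
        for trace in list(session.iter_traces())[:20]:
            counts = [
                len(detect_saccades(trace, v_threshold=v))
                for v in (60.0, 100.0, 160.0, 240.0)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSaccadeMetrics:
    def test_rightward_saccade_metrics(self):
        tr = _trace_with_saccade(onset_ms=150.0, noise=0.05, seed=8,
                                 total_ms=600.0)
        iv = detect_saccades(tr)[0]
        ev = saccade_metrics(tr, iv, jump_time_ms=0.0, target_xy=(7, 0))
        assert ev.amplitude_deg == pytest.approx(7.0, abs=0.1)
        assert min(ev.direction_deg, 360 - ev.direction_deg) <= 2.0
        assert ev.latency_ms == pytest.approx(iv.onset_ms)

    def test_leftward_displacement_has_direction_180(self):
        tr = _trace_with_saccade(onset_ms=200.0, direction=(-1.0, 0.0),
                                 total_ms=600.0)
        iv = detect_saccades(tr)[0]
        ev = saccade_metrics(tr, iv, jump_time_ms=0.0)
        assert ev.direction_deg == pytest.approx(180.0, abs=2.0)

    def test_latency_is_onset_minus_jump_time(self):
        tr = _trace_with_saccade(onset_ms=350.0, total_ms=800.0)
        iv = detect_saccades(tr)[0]
        ev = saccade_metrics(tr, iv, jump_time_ms=200.0)
        assert ev.latency_ms == pytest.approx(iv.onset_ms - 200.0)

    def test_degenerate_interval_rejected(self):
        tr = _trace_with_saccade()
        with pytest.raises(InvalidArgumentError):
            saccade_metrics(
                tr, SaccadeInterval(10, 9, 20.0, 20.0), 0.0
            )

    def test_metrics_invariant_under_translation(self):
        tr = _trace_with_saccade(onset_ms=250.0, total_ms=700.0)
        shifted = EyeTrace(tr.t_ms, tr.x_deg + 3.0, tr.y_deg - 2.0, 500.0)
        iv1 = detect_saccades(tr)[0]
        iv2 = detect_saccades(shifted)[0]
        e1 = saccade_metrics(tr, iv1, 0.0)
        e2 = saccade_metrics(shifted, iv2, 0.0)
        assert e1.onset_ms == e2.onset_ms
        assert e1.amplitude_deg == pytest.approx(e2.amplitude_deg, abs=1e-9)
        assert e1.direction_deg == pytest.approx(e2.direction_deg, abs=1e-9)

    def test_direction_rotates_with_coordinates(self):
        tr = _trace_with_saccade(onset_ms=250.0, total_ms=700.0)
        rot = EyeTrace(tr.t_ms, -tr.y_deg, tr.x_deg, 500.0)  # +90 deg rotation
        e1 = saccade_metrics(tr, detect_saccades(tr)[0], 0.0)
        e2 = saccade_metrics(rot, detect_saccades(rot)[0], 0.0)
        assert (e2.direction_deg - e1.direction_deg) % 360 == pytest.approx(
            90.0, abs=1e-6
        )


def test_detection_recall_and_precision_on_generator(small_null_session):
    """No missed and no spurious task saccades at default noise."""
    s = small_null_session
    sac = build_saccade_table(s)
    gt = s.ground_truth.set_index("trial_id")
    matched_true = matched_det = 0
    for tid, g in sac.groupby("trial_id"):
        close = (g["latency_ms"] - gt.loc[tid, "true_task_latency_ms"]).abs() <= 20
        matched_true += int(close.any())
        matched_det += int(close.sum())
    assert matched_true / len(gt) >= 0.99
    assert matched_det / len(sac) >= 0.99
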