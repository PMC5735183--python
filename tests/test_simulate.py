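"""Generator: main-sequence law, saccade waveform, trial/session structure."""

import numpy as np
import pytest

from oculostim import (
    SimConfig,
    TrialSpec,
    detect_saccades,
    electrode_map_frame,
    main_sequence_params,
    saccade_metrics,
    simulate_session,
    simulate_trial,
    synth_saccade_segment,
)
from oculostim.errors import ConfigurationError, InvalidArgumentError


class TestMainSequence:
    def test_default_values_at_7_deg(self):
        duration, peak_v = main_sequence_params(7.0)
        assert duration == pytest.approx(36.4)
        assert peak_v == pytest.approx(2 * 7 / 0.0364, rel=1e-12)

    def test_strictly_increasing_in_amplitude(self):
        d7, v7 = main_sequence_params(7.0)
        d14, v14 = main_sequence_params(14.0)
        assert d14 == pytest.approx(51.8) and d14 > d7
        assert v14 > v7

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_amplitude_rejected(self, bad):
        with pytest.raises(InvalidArgumentError):
            main_sequence_params(bad)


class TestSaccadeSegment:
    def test_midflight_displacement_is_half_amplitude(self):
        # amplitude chosen so that D/2 falls exactly on the 500 Hz grid
        amp = (4 * 10 - 21) / 2.2  # D = 40 ms
        t, xy = synth_saccade_segment((0, 0), (amp, 0), 0.0, 500.0)
        mid = np.flatnonzero(np.isclose(t, 20.0))[0]
        assert xy[mid, 0] == pytest.approx(amp / 2, abs=1e-9)

    def test_final_sample_lands_on_endpoint(self):
        t, xy = synth_saccade_segment((1.0, -2.0), (8.0, 1.5), 100.0, 500.0)
        assert np.allclose(xy[-1], [8.0, 1.5], atol=1e-9)
        assert np.allclose(xy[0], [1.0, -2.0], atol=1e-9)

    def test_finite_difference_peak_speed_matches_profile(self):
        # the 500 Hz finite-difference peak should be within 3% of the
        # closed-form 2A/D, cross-checked against a dense 100 kHz oracle
        amp = 7.0
        duration, peak = main_sequence_params(amp)
        for rate in (500.0, 100_000.0):
            t, xy = synth_saccade_segment((0, 0), (amp, 0), 0.0, rate)
            v = np.max(np.abs(np.diff(xy[:, 0]) / np.diff(t))) * 1000.0
            tol = 0.03 if rate == 500.0 else 1e-3
            assert v == pytest.approx(peak, rel=tol)

    def test_zero_length_saccade_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synth_saccade_segment((1, 1), (1, 1), 0.0, 500.0)


class TestSimulateTrial:
    def test_identical_seed_gives_bit_identical_trace(self):
        cfg = SimConfig()
        spec = TrialSpec("contra", True, 90, 250)
        tr1, _, _ = simulate_trial(cfg, spec, np.random.default_rng(3))
        tr2, _, _ = simulate_trial(cfg, spec, np.random.default_rng(3))
        assert np.array_equal(tr1.x_deg, tr2.x_deg)
        assert np.array_equal(tr1.y_deg, tr2.y_deg)

    def test_noiseless_task_saccade_amplitude_recovered(self):
        cfg = SimConfig.no_effect(noise_sd_deg=0.0)
        trace, trial, gt = simulate_trial(
            cfg, TrialSpec("contra", False, 0, 100), np.random.default_rng(4)
        )
        intervals = detect_saccades(trace)
        assert len(intervals) == 1
        ev = saccade_metrics(trace, intervals[0], trial["jump_time_ms"], (7, 0))
        assert ev.amplitude_deg == pytest.approx(7.0, abs=0.05)

    def test_certain_evocation_recorded_in_ground_truth(self):
        cfg = SimConfig()
        evoking = cfg.evoking_electrodes[0]
        eid = evoking.electrode_id
        assert evoking.prob_by_current[250] < 1.0
        from dataclasses import replace

        cfg.evoking_electrodes = tuple(
            replace(el, prob_by_current={100: 1.0, 250: 1.0})
            for el in cfg.evoking_electrodes
        )
        _, _, gt = simulate_trial(
            cfg, TrialSpec("ipsi", True, eid, 250), np.random.default_rng(5)
        )
        assert bool(gt["evoked_present"])
        assert 0 <= gt["evoked_onset_ms"] < 100

    def test_missing_effect_map_entry_is_configuration_error(self):
        cfg = SimConfig(effect_map={("caudal", 250, "contra"): 10.0})
        with pytest.raises(ConfigurationError):
            simulate_trial(
                cfg, TrialSpec("ipsi", True, 0, 100), np.random.default_rng(0)
            )


class TestSimulateSession:
    def test_default_session_counts(self):
        cfg = SimConfig()
        assert cfg.n_trials == 96 * 2 * 20 == 3840

    def test_block_structure_and_balance(self, small_null_session):
        trials = small_null_session.trials
        assert len(trials) == 12 * 2 * 20
        assert int(trials["stim"].sum()) == len(trials) // 2
        for _, block in trials.groupby("block_id"):
            assert block["stim"].mean() == 0.5
            n_contra = (block["jump_dir"] == "contra").sum()
            assert abs(n_contra - len(block) / 2) <= 0.5

    def test_electrode_map_splits_grid_in_equal_halves(self):
        emap = electrode_map_frame(SimConfig())
        counts = emap["group"].value_counts()
        assert counts["caudal"] == counts["rostral"] == 48

    def test_odd_block_size_with_half_stim_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(trials_per_block=7)

    def test_session_determinism(self, small_null_config):
        s1 = simulate_session(small_null_config, seed=9)
        s2 = simulate_session(small_null_config, seed=9)
        assert np.array_equal(s1.x, s2.x) and np.array_equal(s1.y, s2.y)
        assert s1.trials.equals(s2.trials)

    def test_latency_marginals_match_configured_moments(self):
        # empirical mean latency per direction converges to mu + tau
        cfg = SimConfig.no_effect(
            n_electrodes=100, grid_shape=(2, 50), currents_uA=(100,),
            trials_per_block=40, baseline_contra_advantage_ms=26.0,
        )
        s = simulate_session(cfg, seed=22)
        gt = s.ground_truth.merge(s.trials, on="trial_id")
        se = np.sqrt(cfg.latency_sigma_ms**2 + cfg.latency_tau_ms**2)
        for direction in ("contra", "ipsi"):
            lat = gt.loc[gt["jump_dir"] == direction, "true_task_latency_ms"]
            expected = cfg.latency_mu_ms(direction) + cfg.latency_tau_ms
            assert abs(lat.mean() - expected) < 3 * se / np.sqrt(len(lat))

    def test_every_trial_has_exactly_one_ground_truth_row(self, small_null_session):
        s = small_null_session
        assert sorted(s.ground_truth["trial_id"]) == sorted(s.trials["trial_id"])
        assert not s.ground_truth["trial_id"].duplicated().any()
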