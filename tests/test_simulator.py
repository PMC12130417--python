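import dataclasses

import numpy as np
import pytest

from oxyvib.dsp import process_recording, windowed_mean
from oxyvib.pipeline import extract_at_timepoint
from oxyvib.simulator import (
    PumpModel,
    SimCohortConfig,
    ThrombosisModel,
    calibrate,
    detection_lead_time,
    draw_subject_params,
    expected_response_fractions,
    simulate_cohort,
    simulate_recording,
    subject_seed,
)

from conftest import pure_tone_calibration, tone_config


class TestCalibration:
    def test_reproduces_target_relative_changes_in_expectation(self):
        cfg = SimCohortConfig.compact(
            seed=0, amp_sigma_ln=0.0, noise_sigma_ln=0.0, gain_sigma_ln=0.0
        )
        cal = calibrate(cfg)
        s = simulate_recording(draw_subject_params(cfg, 0), cfg, cal)
        assert s.expected_drms_pct["medium"] == pytest.approx(23.1, abs=1e-9)
        assert s.expected_drms_pct["high"] == pytest.approx(135.0, abs=1e-9)
        assert s.expected_drms_pct["t15"] == pytest.approx(6.4, abs=1e-9)
        assert s.expected_rms_g["baseline"] == pytest.approx(cfg.rms_baseline_g)

    def test_baseline_power_split_is_consistent(self):
        cfg = SimCohortConfig.compact()
        cal = calibrate(cfg)
        harm = sum(a**2 / 2 for a in cal.harmonic_amplitudes)
        assert harm == pytest.approx(cal.harmonic_power, rel=1e-12)
        assert cal.harmonic_power + cal.noise_power_inband == pytest.approx(
            cfg.rms_baseline_g**2, rel=1e-12
        )

    def test_nyquist_guard_on_harmonics(self):
        pump = PumpModel(rpm=12000.0, harmonic_amplitudes=(0.1,) * 3,
                         harmonic_phases=(0.0,) * 3)
        with pytest.raises(ValueError, match="Nyquist"):
            pump.validate_rate(1000.0)


class TestThrombosisModel:
    def test_gain_zero_before_onset_monotone_saturating_after(self):
        m = ThrombosisModel(onset_s=100.0, rise_time_s=20.0, max_gain=2.0)
        t = np.linspace(0, 500, 2001)
        g = m.gain(t)
        assert np.all(g[t < 100.0] == 0.0)
        assert np.all(np.diff(g) >= 0)
        assert g[-1] == pytest.approx(2.0, rel=1e-6)


class TestSimulateRecording:
    def test_zero_effects_give_all_zero_axes(self):
        cfg = tone_config(gravity_vector=(0.0, 0.0, 0.0))
        cal = dataclasses.replace(pure_tone_calibration(), harmonic_amplitudes=(0.0,))
        s = simulate_recording(draw_subject_params(cfg, 0), cfg, cal)
        assert np.all(s.recording.gx == 0)
        assert np.all(s.recording.gy == 0)
        assert np.all(s.recording.gz == 0)

    def test_single_noiseless_harmonic_matches_analytic_rms(self):
        # rpm 3000 -> 50 Hz tone of amplitude A riding on the 1 g offset;
        # after the chain every window RMS is exactly A/sqrt(2)
        amp = 0.1
        cfg = tone_config(rpm=3000.0)
        s = simulate_recording(draw_subject_params(cfg, 0), cfg, pure_tone_calibration(amp))
        series = process_recording(s.recording, window_s=30.0)
        np.testing.assert_allclose(series.values, amp / np.sqrt(2), atol=1e-6)

    def test_identical_seed_identical_recording(self):
        cfg = tone_config()
        p = draw_subject_params(cfg, 0)
        a = simulate_recording(p, cfg)
        b = simulate_recording(p, cfg)
        np.testing.assert_array_equal(a.recording.gx, b.recording.gx)
        np.testing.assert_array_equal(
            a.recording.aux_channels["delta_p_oxy"],
            b.recording.aux_channels["delta_p_oxy"],
        )

    def test_pipeline_recovers_expected_rms_per_timepoint(self):
        cfg = SimCohortConfig.compact(seed=5)
        cal = calibrate(cfg)
        s = simulate_recording(draw_subject_params(cfg, 0), cfg, cal)
        series = process_recording(s.recording, window_s=cfg.window_s)
        for label, t in cfg.extraction_times().items():
            got = extract_at_timepoint(series, t)
            assert got == pytest.approx(s.expected_rms_g[label], rel=0.02), label

    def test_sub_band_drift_contributes_nothing_post_filter(self):
        cfg = tone_config(rpm=3000.0, drift_amplitude_g=0.0)
        cfg_drift = dataclasses.replace(cfg, drift_amplitude_g=0.05)
        cal = pure_tone_calibration()
        p = draw_subject_params(cfg, 0)
        clean = process_recording(simulate_recording(p, cfg, cal).recording).values
        drift = process_recording(simulate_recording(p, cfg_drift, cal).recording).values
        np.testing.assert_allclose(drift, clean, atol=1e-6)

    def test_fundamental_in_band_at_3000_rpm(self):
        cfg = tone_config(rpm=3000.0)
        pump = PumpModel(rpm=3000.0, harmonic_amplitudes=(0.1,), harmonic_phases=(0.0,))
        assert 10.0 < pump.fundamental_hz < 375.0
        # and the tone survives the filter: window RMS stays ~A/sqrt(2)
        s = simulate_recording(draw_subject_params(cfg, 0), cfg, pure_tone_calibration())
        v = process_recording(s.recording).values
        assert v.min() > 0.9 * 0.1 / np.sqrt(2)

    def test_rpm_shift_preserves_harmonic_rms(self):
        # same amplitudes, different in-band fundamental: the RMS metric
        # responds to amplitude, not to frequency placement within the band
        cal = pure_tone_calibration()
        p_lo = simulate_recording(
            draw_subject_params(tone_config(rpm=3000.0), 0), tone_config(rpm=3000.0), cal
        )
        p_hi = simulate_recording(
            draw_subject_params(tone_config(rpm=4200.0), 0), tone_config(rpm=4200.0), cal
        )
        a = process_recording(p_lo.recording).values
        b = process_recording(p_hi.recording).values
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_larger_max_gain_raises_post_onset_rms(self):
        cfg = SimCohortConfig.compact(seed=9, gain_sigma_ln=0.0,
                                      amp_sigma_ln=0.0, noise_sigma_ln=0.0)
        cal = calibrate(cfg)
        cal_big = dataclasses.replace(cal, max_gain=2.0 * cal.max_gain)
        p = draw_subject_params(cfg, 0)
        small = simulate_recording(p, cfg, cal)
        big = simulate_recording(p, cfg, cal_big)
        for label in cfg.reversal_labels:
            assert big.expected_rms_g[label] > small.expected_rms_g[label]
        # and measured, not just expected
        t15 = cfg.extraction_times()["t15"]
        rms_small = extract_at_timepoint(process_recording(small.recording), t15)
        rms_big = extract_at_timepoint(process_recording(big.recording), t15)
        assert rms_big > rms_small

    def test_pressure_channel_baseline_tracks_flow(self):
        cfg = tone_config(include_hemodynamics=False)
        s = simulate_recording(draw_subject_params(cfg, 0), cfg, pure_tone_calibration())
        dp = s.recording.aux_channels["delta_p_oxy"]
        expected = cfg.pressure.baseline(cfg.pump_flow_lpm[0])
        assert np.mean(dp[:20000]) == pytest.approx(expected, abs=0.05)


class TestSimulateCohort:
    def test_cohort_cardinality_and_files(self, tmp_path):
        cohort = simulate_cohort(tone_config(n_subjects=7), out_dir=tmp_path)
        assert len(cohort.subjects) == 7
        assert cohort.manifest.n_subjects == 7
        assert len(list(tmp_path.glob("*_recording.csv"))) == 7
        assert len(list(tmp_path.glob("*_timeline.csv"))) == 7
        assert (tmp_path / "manifest.yaml").exists()
        assert (tmp_path / "ground_truth.json").exists()

    def test_seeded_cohorts_are_byte_identical(self, tmp_path):
        cfg = tone_config(n_subjects=2, seed=3)
        simulate_cohort(cfg, out_dir=tmp_path / "a")
        simulate_cohort(cfg, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_zero_spread_makes_subjects_identical_up_to_noise(self):
        cfg = tone_config(
            n_subjects=3, amp_sigma_ln=0.0, noise_sigma_ln=0.0, gain_sigma_ln=0.0
        )
        cohort = simulate_cohort(cfg)
        truths = [s.expected_rms_g for s in cohort.subjects]
        assert truths[0] == truths[1] == truths[2]
        # distinct sub-seeds still give distinct noise realizations
        assert not np.array_equal(
            cohort.subjects[0].recording.gx, cohort.subjects[1].recording.gx
        )

    def test_subject_seeds_deterministic_and_in_range(self):
        seeds = [subject_seed(123, i) for i in range(10)]
        assert seeds == [subject_seed(123, i) for i in range(10)]
        assert len(set(seeds)) == 10
        assert all(0 <= s < 2**31 for s in seeds)

    def test_ground_truth_records_parameters(self):
        cohort = simulate_cohort(tone_config(n_subjects=2))
        gt = cohort.ground_truth
        assert gt["n_subjects"] == 2
        assert {"amp_mult", "noise_mult", "gain_mult", "expected_drms_pct"} <= set(
            gt["subjects"][0]
        )


class TestDetectionLeadTime:
    def _series(self, cfg, subject):
        rms = process_recording(subject.recording, window_s=cfg.window_s)
        dp = windowed_mean(
            subject.recording.aux_channels["delta_p_oxy"], cfg.fs, cfg.window_s
        )
        return rms, dp

    def test_lagged_pressure_yields_positive_lead(self):
        cfg = SimCohortConfig.lead_time_study(seed=4, lag_s=900.0)
        rms_pl, dp_pl = expected_response_fractions(cfg)
        s = simulate_cohort(dataclasses.replace(cfg, n_subjects=1)).subjects[0]
        rms, dp = self._series(cfg, s)
        r = detection_lead_time(rms, dp, cfg.reversal_time_s, 0.5 * rms_pl, 0.5 * dp_pl)
        assert r.t_rms_cross is not None and r.t_dp_cross is not None
        assert r.lead_s > 0
        assert r.lead_s == pytest.approx(900.0, abs=3 * cfg.window_s)

    def test_zero_lag_with_matched_shapes_gives_small_lead(self):
        cfg = SimCohortConfig.lead_time_study(seed=4, lag_s=0.0)
        rms_pl, dp_pl = expected_response_fractions(cfg)
        s = simulate_cohort(dataclasses.replace(cfg, n_subjects=1)).subjects[0]
        rms, dp = self._series(cfg, s)
        r = detection_lead_time(rms, dp, cfg.reversal_time_s, 0.5 * rms_pl, 0.5 * dp_pl)
        # matched 0.5x-plateau thresholds map to slightly different points of
        # the shared logistic, so allow a couple of windows of discretization
        assert abs(r.lead_s) <= 2 * cfg.window_s

    def test_absent_crossing_is_open_outcome(self):
        cfg = SimCohortConfig.lead_time_study(seed=4, lag_s=900.0)
        rms_pl, _ = expected_response_fractions(cfg)
        s = simulate_cohort(dataclasses.replace(cfg, n_subjects=1)).subjects[0]
        rms, dp = self._series(cfg, s)
        # impossible pressure threshold: channel never crosses
        r = detection_lead_time(rms, dp, cfg.reversal_time_s, 0.5 * rms_pl, 50.0)
        assert r.t_dp_cross is None
        assert r.censored
        assert r.lead_s > 0

    def test_missing_baseline_windows_rejected(self):
        cfg = SimCohortConfig.lead_time_study(seed=4)
        s = simulate_cohort(dataclasses.replace(cfg, n_subjects=1)).subjects[0]
        rms, dp = self._series(cfg, s)
        with pytest.raises(ValueError, match="baseline"):
            detection_lead_time(rms, dp, cfg.reversal_time_s, 0.05, 0.05,
                                baseline_start_s=cfg.reversal_time_s)
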