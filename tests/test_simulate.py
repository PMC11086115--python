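import numpy as np
import pytest

from fatigueforest.config import DEFAULT_CONFIG
from fatigueforest.features import WelchSpec, welch_psd, band_power, detect_r_peaks, time_domain_hrv
from fatigueforest.simulate import (BASELINE_SHARES, ECGStateParams, SimulationSpec,
                                    generate_dataset, simulate_ecg, simulate_eeg,
                                    solve_modulation_amplitudes)

FS = 250.0


def measured_shares(x, fs=FS):
    f, p = welch_psd(x, fs, WelchSpec(nperseg=min(500, x.size)))
    edges = {"delta": (0.5, 4), "theta": (4, 8), "alpha": (8, 13),
             "beta": (13, 30), "gamma": (30, 45)}
    powers = {b: band_power(f, p, lo, hi) for b, (lo, hi) in edges.items()}
    total = sum(powers.values())
    return {b: v / total for b, v in powers.items()}


class TestEEG:
    def test_fatigue_raises_theta_share(self):
        spec = SimulationSpec(eeg_noise_uV=0.0, hum_amp_eeg_uV=0.0, drift_amp_eeg_uV=0.0)
        diffs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            sh_y = measured_shares(simulate_eeg("Y", spec, rng, duration=60.0))
            rng = np.random.default_rng(seed)
            sh_n = measured_shares(simulate_eeg("N", spec, rng, duration=60.0))
            diffs.append(sh_y["theta"] - sh_n["theta"])
        assert np.mean(diffs) == pytest.approx(0.10, abs=0.05)

    def test_realized_shares_match_spec(self):
        spec = SimulationSpec(eeg_noise_uV=0.0, hum_amp_eeg_uV=0.0, drift_amp_eeg_uV=0.0)
        rng = np.random.default_rng(0)
        sh = measured_shares(simulate_eeg("N", spec, rng, duration=60.0))
        for b, target in spec.shares("N").items():
            assert sh[b] == pytest.approx(target, abs=0.05), b

    def test_no_hum_no_mains_peak(self):
        spec = SimulationSpec(hum_amp_eeg_uV=0.0)
        rng = np.random.default_rng(1)
        x = simulate_eeg("N", spec, rng, duration=30.0)
        f, p = welch_psd(x, FS)
        mains = band_power(f, p, 49, 51)
        neighbours = band_power(f, p, 45, 49) + band_power(f, p, 51, 55)
        assert mains < neighbours

    def test_deterministic_given_seed(self):
        spec = SimulationSpec()
        a = simulate_eeg("N", spec, np.random.default_rng(3), duration=10.0)
        b = simulate_eeg("N", spec, np.random.default_rng(3), duration=10.0)
        np.testing.assert_array_equal(a, b)

    def test_invalid_shares_rejected(self):
        spec = SimulationSpec(eeg_effect={"beta": -0.30})
        with pytest.raises(ValueError, match="share"):
            simulate_eeg("Y", spec, np.random.default_rng(0), duration=5.0)


class TestECG:
    def test_rmssd_target_recovered(self):
        spec = SimulationSpec()
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ecg, _ = simulate_ecg("N", spec, rng, duration=60.0)
            rr = detect_r_peaks(ecg, FS)
            vals.append(time_domain_hrv(rr)[1])
        assert np.all(np.abs(np.array(vals) - 40.0) <= 10.0)  # within 25%

    def test_fatigue_raises_lf_hf(self):
        from fatigueforest.features import freq_domain_hrv
        spec = SimulationSpec()
        wins = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            ecg_y, _ = simulate_ecg("Y", spec, rng, duration=120.0)
            rng = np.random.default_rng(seed)
            ecg_n, _ = simulate_ecg("N", spec, rng, duration=120.0)
            ratio_y = freq_domain_hrv(detect_r_peaks(ecg_y, FS))[2]
            ratio_n = freq_domain_hrv(detect_r_peaks(ecg_n, FS))[2]
            wins += ratio_y > ratio_n
        assert wins >= 7

    def test_zero_modulation_zero_noise_is_metronomic(self):
        spec = SimulationSpec(rr_jitter=0.0, ecg_noise_mV=0.0, drift_amp_ecg_mV=0.0,
                              hum_amp_ecg_mV=0.0,
                              ecg_n=ECGStateParams(rr_mean=0.8, rmssd=0.0, lf_hf=1.0))
        rng = np.random.default_rng(0)
        ecg, truth = simulate_ecg("N", spec, rng, duration=30.0)
        rr = truth.rr_intervals
        assert np.allclose(rr, 0.8, atol=1 / FS + 1e-9)
        assert time_domain_hrv(truth)[1] <= 1000.0 / FS  # grid-quantised zero

    def test_modulation_amplitude_solver(self):
        # brute-force check of the closed form against a simulated tachogram
        p = ECGStateParams(rr_mean=0.8, rmssd=40.0, lf_hf=1.5)
        a_l, a_h = solve_modulation_amplitudes(p)
        t = np.arange(0.0, 400.0, p.rr_mean)
        rr = (p.rr_mean + a_l * np.sin(2 * np.pi * 0.1 * t)
              + a_h * np.sin(2 * np.pi * 0.3 * t + 1.0))
        rmssd = np.sqrt(np.mean(np.diff(rr) ** 2)) * 1000
        assert rmssd == pytest.approx(40.0, rel=0.1)

    def test_ground_truth_peaks_on_sample_grid(self):
        spec = SimulationSpec()
        _, truth = simulate_ecg("Y", spec, np.random.default_rng(4), duration=20.0)
        np.testing.assert_allclose(truth.r_peak_times * FS,
                                   np.round(truth.r_peak_times * FS), atol=1e-9)


class TestGenerateDataset:
    def test_cohort_structure_and_kss_consistency(self):
        spec = SimulationSpec(n_subjects=2, segments_per_state=(2, 1),
                              duration=110.0, seed=5)
        cfg = DEFAULT_CONFIG.with_(step=10.0)
        segments, manifest = generate_dataset(spec, config=cfg)
        assert len(segments) == 6 and len(manifest) == 6
        for seg, man in zip(segments, manifest):
            assert seg.label == man["state"]
            if seg.label == "N":
                assert 1 <= seg.recording.kss <= 5
            else:
                assert 6 <= seg.recording.kss <= 9
            assert seg.recording.duration == pytest.approx(50.0)

    def test_byte_identical_given_seed(self):
        spec = SimulationSpec(n_subjects=1, segments_per_state=(1, 1),
                              duration=110.0, seed=9)
        cfg = DEFAULT_CONFIG.with_(step=10.0)
        a, _ = generate_dataset(spec, config=cfg)
        b, _ = generate_dataset(spec, config=cfg)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.recording.eeg, s2.recording.eeg)
            np.testing.assert_array_equal(s1.recording.ecg, s2.recording.ecg)

    def test_parameter_recovery_hr(self):
        spec = SimulationSpec(n_subjects=2, segments_per_state=(1, 1),
                              duration=110.0, seed=21, subject_rr_sd=0.0)
        cfg = DEFAULT_CONFIG.with_(step=10.0)
        segments, manifest = generate_dataset(spec, config=cfg)
        from fatigueforest.ecg import clean_ecg_for_peaks
        for seg, man in zip(segments, manifest):
            rr = detect_r_peaks(clean_ecg_for_peaks(seg.recording.ecg, cfg), FS)
            hr = time_domain_hrv(rr)[0]
            assert hr == pytest.approx(60.0 / man["rr_mean"], abs=2.0)
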