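import numpy as np
import pytest

from fatigueforest.config import DEFAULT_CONFIG
from fatigueforest.features import (DetectionError, FEATURE_NAMES, RRSeries,
                                    WelchSpec, detect_r_peaks, differential_entropy,
                                    eeg_features, extract_all, freq_domain_hrv,
                                    time_domain_hrv, welch_psd)
from fatigueforest.simulate import SimulationSpec, generate_dataset, simulate_ecg

FS = 250.0


def rr_from_intervals(intervals, t0=0.0):
    times = t0 + np.concatenate([[0.0], np.cumsum(intervals)])
    return RRSeries(times)


class TestWelch:
    def test_white_noise_parseval(self, rng):
        x = rng.standard_normal(25_000)
        f, p = welch_psd(x, FS)
        total = np.sum(p) * (f[1] - f[0])
        assert total == pytest.approx(np.var(x), rel=0.1)

    def test_sinusoid_peak_power(self):
        a = 2.0
        t = np.arange(0, 40, 1 / FS)
        x = a * np.sin(2 * np.pi * 10.0 * t)
        f, p = welch_psd(x, FS)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=0.5)
        assert np.sum(p) * (f[1] - f[0]) == pytest.approx(a ** 2 / 2, rel=0.05)

    def test_signal_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.ones(100), FS, WelchSpec(nperseg=500))

    def test_estimator_variance_halves_with_double_segments(self, rng):
        # averaging L periodograms scales estimator variance ~ 1/L
        spreads = {}
        for n_seg in (8, 16):
            vals = []
            for seed in range(30):
                x = np.random.default_rng(seed).standard_normal(256 * n_seg)
                f, p = welch_psd(x, FS, WelchSpec(nperseg=256, overlap=0.0))
                vals.append(p[20])
            spreads[n_seg] = np.var(vals)
        assert spreads[16] < spreads[8]


class TestEEGFeatures:
    def test_gaussian_closed_forms(self, rng):
        x = rng.standard_normal(10_000)
        assert differential_entropy(x) == pytest.approx(2.047, abs=0.05)
        feats = eeg_features({b: rng.standard_normal(10_000) for b in
                              ("delta", "theta", "alpha", "beta", "gamma")}, FS)
        for b in ("delta", "theta", "alpha", "beta", "gamma"):
            assert feats[f"ks_{b}"] == pytest.approx(3.0, abs=0.2)
            assert feats[f"sk_{b}"] == pytest.approx(0.0, abs=0.1)

    def test_two_point_symmetric_moments(self):
        from scipy import stats
        x = np.tile([1.0, -1.0], 500)
        assert stats.kurtosis(x, fisher=False) == pytest.approx(1.0)
        assert stats.skew(x) == pytest.approx(0.0)

    def test_de_monotone_in_variance(self, rng):
        x = rng.standard_normal(5000)
        assert differential_entropy(2.0 * x) > differential_entropy(x)

    def test_ks_sk_scale_invariant(self, rng):
        from scipy import stats
        x = rng.gamma(2.0, size=5000)
        for a in (0.1, 7.3):
            assert stats.kurtosis(a * x, fisher=False) == pytest.approx(
                stats.kurtosis(x, fisher=False), rel=1e-9)
            assert stats.skew(a * x) == pytest.approx(stats.skew(x), rel=1e-9)

    def test_constant_band_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            differential_entropy(np.ones(100))


class TestRPeaks:
    def test_strict_rhythm_peak_count_and_intervals(self):
        spec = SimulationSpec(rr_jitter=0.0, ecg_noise_mV=0.005,
                              drift_amp_ecg_mV=0.0, hum_amp_ecg_mV=0.0)
        # zero LF/HF modulation: fixed 0.8 s rhythm
        from fatigueforest.simulate import ECGStateParams
        spec = SimulationSpec(rr_jitter=0.0, ecg_noise_mV=0.005,
                              drift_amp_ecg_mV=0.0, hum_amp_ecg_mV=0.0,
                              ecg_n=ECGStateParams(rr_mean=0.8, rmssd=0.0, lf_hf=1.5))
        rng = np.random.default_rng(0)
        ecg, truth = simulate_ecg("N", spec, rng, duration=30.0)
        rr = detect_r_peaks(ecg, FS)
        assert rr.r_peak_times.size in (36, 37, 38)
        assert np.all((rr.rr_intervals >= 0.79) & (rr.rr_intervals <= 0.81))

    def test_flat_line_raises_detection_error(self):
        with pytest.raises(DetectionError):
            detect_r_peaks(np.zeros(5000), FS)

    def test_jittered_rhythm_matches_ground_truth(self):
        spec = SimulationSpec(ecg_noise_mV=0.01, drift_amp_ecg_mV=0.0,
                              hum_amp_ecg_mV=0.0)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            ecg, truth = simulate_ecg("N", spec, rng, duration=60.0)
            det = detect_r_peaks(ecg, FS)
            # compare RR interval sequences over the common (edge-trimmed) beats
            t_true = truth.r_peak_times
            keep = (t_true >= det.r_peak_times[0] - 0.05) & \
                   (t_true <= det.r_peak_times[-1] + 0.05)
            rr_true = np.diff(t_true[keep])
            rr_det = det.rr_intervals
            assert rr_det.size == rr_true.size
            assert np.max(np.abs(rr_det - rr_true)) <= 2.0 / FS + 1e-9

    def test_refractory_period_enforced(self):
        spec = SimulationSpec()
        rng = np.random.default_rng(2)
        ecg, _ = simulate_ecg("Y", spec, rng, duration=30.0)
        rr = detect_r_peaks(ecg, FS)
        assert np.all(rr.rr_intervals >= 0.25)


class TestHRV:
    def test_constant_rhythm(self):
        hr, rmssd = time_domain_hrv(rr_from_intervals([1.0, 1.0, 1.0]))
        assert hr == pytest.approx(60.0) and rmssd == pytest.approx(0.0)

    def test_fast_rhythm_hr(self):
        hr, _ = time_domain_hrv(rr_from_intervals([0.5, 0.5]))
        assert hr == pytest.approx(120.0)

    def test_rmssd_closed_form(self):
        hr, rmssd = time_domain_hrv(rr_from_intervals([0.800, 0.810, 0.790, 0.805]))
        assert rmssd == pytest.approx(np.sqrt((10 ** 2 + 20 ** 2 + 15 ** 2) / 3), abs=1e-9)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            time_domain_hrv(rr_from_intervals([0.8]))

    @pytest.mark.parametrize("mod_freq,dominant", [(0.1, "lf"), (0.3, "hf")])
    def test_single_tone_modulation_dominates_band(self, mod_freq, dominant):
        times = [0.0]
        while times[-1] < 120.0:
            t = times[-1]
            times.append(t + 0.8 + 0.05 * np.sin(2 * np.pi * mod_freq * t))
        lf, hf, ratio = freq_domain_hrv(RRSeries(np.array(times)))
        if dominant == "lf":
            assert lf >= 0.8
        else:
            assert hf >= 0.8
        assert ratio == pytest.approx(lf / hf, abs=1e-9)
        assert lf + hf <= 1.0 + 1e-6

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            freq_domain_hrv(rr_from_intervals([0.8] * 10))


@pytest.fixture(scope="module")
def segment_pair():
    cfg = DEFAULT_CONFIG.with_(step=5.0)
    spec = SimulationSpec(n_subjects=1, segments_per_state=(1, 1),
                          duration=110.0, seed=7)
    segments, _ = generate_dataset(spec, config=cfg)
    return segments  # [N, Y]


class TestExtractAll:
    def test_vector_shape_and_composition(self, segment_pair):
        seg = segment_pair[0]
        vec = extract_all(seg)
        assert vec.shape == (25,)
        assert np.all(np.isfinite(vec))
        # positions 21-22 (indices 20, 21) are the time-domain HRV outputs
        from fatigueforest.ecg import clean_ecg_for_peaks
        rr = detect_r_peaks(clean_ecg_for_peaks(seg.recording.ecg), FS)
        hr, rmssd = time_domain_hrv(rr)
        assert vec[20] == pytest.approx(hr)
        assert vec[21] == pytest.approx(rmssd)

    def test_deterministic(self, segment_pair):
        v1 = extract_all(segment_pair[0])
        v2 = extract_all(segment_pair[0])
        np.testing.assert_array_equal(v1, v2)

    def test_fatigue_raises_theta_power(self, segment_pair):
        v_n = extract_all(segment_pair[0])
        v_y = extract_all(segment_pair[1])
        i_theta = FEATURE_NAMES.index("psd_theta")
        i_total = [FEATURE_NAMES.index(f"psd_{b}") for b in
                   ("delta", "theta", "alpha", "beta", "gamma")]
        share_n = v_n[i_theta] / v_n[i_total].sum()
        share_y = v_y[i_theta] / v_y[i_total].sum()
        assert share_y > share_n
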