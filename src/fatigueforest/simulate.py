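"""Synthetic labelled EEG/ECG recordings with controllable fatigue structure.

The generator emulates the acquisition protocol the pipeline targets:
dual-channel 250 Hz segments (default 5 min), one KSS self-report each.
EEG is a mixture of band-limited Gaussian processes whose relative band
powers shift with the fatigue state (fatigued raises the theta and alpha
shares, lowers beta and gamma).  ECG is a PQRST Gaussian-bump template train
driven by an R-R process with LF (0.1 Hz) and HF (0.3 Hz) sinusoidal
modulation whose amplitudes are solved analytically to hit per-state RMSSD
and LF/HF targets.  Both channels carry additive white noise, slow baseline
drift and optional 50 Hz mains hum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import BAND_NAMES, PipelineConfig, DEFAULT_CONFIG
from .features import RRSeries
from .io import LabeledSegment, Recording, trim_and_label

#: Non-fatigued relative band-power shares (delta..gamma); sum to 1.
BASELINE_SHARES = {"delta": 0.25, "theta": 0.15, "alpha": 0.25, "beta": 0.25, "gamma": 0.10}

#: Fatigue shift of each share: theta/alpha up, beta/gamma down, sums to 0.
DEFAULT_EEG_EFFECT = {"delta": 0.0, "theta": 0.10, "alpha": 0.10, "beta": -0.15, "gamma": -0.05}

LF_MOD_HZ, HF_MOD_HZ = 0.1, 0.3


@dataclass(frozen=True)
class ECGStateParams:
    """Per-state R-R process targets."""

    rr_mean: float        # s
    rmssd: float          # ms
    lf_hf: float          # dimensionless power ratio


@dataclass(frozen=True)
class SimulationSpec:
    """Study-condition defaults for the synthetic cohort.

    20 subjects with 13 segments each (7 non-fatigued, 6 fatigued) of 300 s
    at 250 Hz mirror the scale of the emulated acquisition campaign (260
    segments).  Fatigue raises theta/alpha EEG shares by +0.10 each and
    lowers beta/gamma by -0.15/-0.05; cardiac effects are a slower, steadier
    rhythm (RR 0.8 -> 0.9 s, RMSSD 40 -> 20 ms) with raised sympathovagal
    balance (LF/HF 1.5 -> 3.0).
    """

    n_subjects: int = 20
    segments_per_state: tuple[int, int] = (7, 6)   # (N, Y) per subject
    duration: float = 300.0                        # s
    fs: float = 250.0
    eeg_total_rms: float = 30.0                    # uV, band-mixture RMS
    eeg_effect: dict = field(default_factory=lambda: dict(DEFAULT_EEG_EFFECT))
    ecg_n: ECGStateParams = ECGStateParams(rr_mean=0.8, rmssd=40.0, lf_hf=1.5)
    ecg_y: ECGStateParams = ECGStateParams(rr_mean=0.9, rmssd=20.0, lf_hf=3.0)
    eeg_noise_uV: float = 5.0                      # white noise sigma
    ecg_noise_mV: float = 0.03
    drift_amp_eeg_uV: float = 10.0
    drift_amp_ecg_mV: float = 0.15
    drift_freq: float = 0.2                        # Hz (0.1-0.3 Hz drift band)
    hum_amp_eeg_uV: float = 2.0
    hum_amp_ecg_mV: float = 0.03
    hum_freq: float = 50.0
    rr_jitter: float = 0.002                       # s, white beat-to-beat jitter
    subject_rr_sd: float = 0.02                    # s, between-subject RR offset
    seed: int = 0

    def shares(self, state: str) -> dict[str, float]:
        """Band-power shares for state 'N' or 'Y' (always sum to 1)."""
        base = dict(BASELINE_SHARES)
        if state == "Y":
            base = {b: base[b] + self.eeg_effect.get(b, 0.0) for b in base}
        total = sum(base.values())
        if any(v <= 0 for v in base.values()):
            raise ValueError(f"state {state}: non-positive band share in {base}")
        return {b: v / total for b, v in base.items()}

    def ecg_params(self, state: str) -> ECGStateParams:
        return self.ecg_y if state == "Y" else self.ecg_n


def _band_edges(config: PipelineConfig) -> dict[str, tuple[float, float]]:
    return {b.name: (b.lo, b.hi) for b in config.bands}


def simulate_eeg(state: str, spec: SimulationSpec, rng: np.random.Generator,
                 duration: float | None = None,
                 config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Band-structured EEG (uV) for one segment of the given fatigue state."""
    shares = spec.shares(state)
    n = int(round((duration or spec.duration) * spec.fs))
    total_power = spec.eeg_total_rms ** 2
    x = np.zeros(n)
    edges = _band_edges(config)
    for name in BAND_NAMES:
        lo, hi = edges[name]
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=spec.fs, output="sos")
        comp = sps.sosfiltfilt(sos, rng.standard_normal(n))
        comp /= max(np.std(comp), 1e-12)
        x += comp * np.sqrt(shares[name] * total_power)
    t = np.arange(n) / spec.fs
    x += spec.eeg_noise_uV * rng.standard_normal(n)
    x += spec.drift_amp_eeg_uV * np.sin(2 * np.pi * spec.drift_freq * t + rng.uniform(0, 2 * np.pi))
    if spec.hum_amp_eeg_uV:
        x += spec.hum_amp_eeg_uV * np.sin(2 * np.pi * spec.hum_freq * t + rng.uniform(0, 2 * np.pi))
    return x


def solve_modulation_amplitudes(p: ECGStateParams) -> tuple[float, float]:
    """LF/HF sinusoid amplitudes (s) hitting the RMSSD and LF/HF targets.

    For a sinusoid of amplitude a and frequency f sampled every T seconds,
    successive differences have mean square ``2 a^2 sin^2(pi f T)``; with the
    LF/HF power ratio fixed at ``rho = a_L^2 / a_H^2`` the RMSSD target gives
    a closed form for both amplitudes.
    """
    T = p.rr_mean
    rho = p.lf_hf
    s_l = np.sin(np.pi * LF_MOD_HZ * T)
    s_h = np.sin(np.pi * HF_MOD_HZ * T)
    r2 = (p.rmssd / 1000.0) ** 2
    a_h = np.sqrt(r2 / (2.0 * (rho * s_l ** 2 + s_h ** 2)))
    a_l = np.sqrt(rho) * a_h
    return float(a_l), float(a_h)


def _pqrst_template(fs: float) -> tuple[np.ndarray, int]:
    """PQRST beat as five Gaussian bumps; returns (template, R index)."""
    # (centre s rel. R, amplitude mV, width s)
    waves = [(-0.20, 0.10, 0.025), (-0.03, -0.12, 0.010), (0.0, 1.0, 0.012),
             (0.03, -0.25, 0.010), (0.25, 0.30, 0.040)]
    t = np.arange(-0.35, 0.45, 1.0 / fs)
    y = np.zeros_like(t)
    for c, a, w in waves:
        y += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    r_idx = int(np.argmin(np.abs(t)))
    return y, r_idx


def simulate_ecg(state: str, spec: SimulationSpec, rng: np.random.Generator,
                 duration: float | None = None, rr_mean: float | None = None
                 ) -> tuple[np.ndarray, RRSeries]:
    """PQRST pulse-train ECG (mV) plus the ground-truth R-peak series."""
    p = spec.ecg_params(state)
    mean_rr = rr_mean if rr_mean is not None else p.rr_mean
    dur = duration or spec.duration
    a_l, a_h = solve_modulation_amplitudes(p)
    phi_l, phi_h = rng.uniform(0, 2 * np.pi, size=2)

    beats = [float(rng.uniform(0, mean_rr))]
    while True:
        t = beats[-1]
        rr = (mean_rr
              + a_l * np.sin(2 * np.pi * LF_MOD_HZ * t + phi_l)
              + a_h * np.sin(2 * np.pi * HF_MOD_HZ * t + phi_h)
              + spec.rr_jitter * rng.standard_normal())
        if rr <= 0.25:
            raise ValueError(f"R-R modulation produced an interval of {rr:.3f} s <= 0.25 s")
        if t + rr > dur:
            break
        beats.append(t + rr)
    beat_times = np.asarray(beats)

    n = int(round(dur * spec.fs))
    x = np.zeros(n)
    template, r_idx = _pqrst_template(spec.fs)
    for bt in beat_times:
        i0 = int(round(bt * spec.fs)) - r_idx
        lo, hi = max(0, i0), min(n, i0 + template.size)
        if lo < hi:
            x[lo:hi] += template[lo - i0: hi - i0]
    t = np.arange(n) / spec.fs
    x += spec.ecg_noise_mV * rng.standard_normal(n)
    x += spec.drift_amp_ecg_mV * np.sin(2 * np.pi * spec.drift_freq * t + rng.uniform(0, 2 * np.pi))
    if spec.hum_amp_ecg_mV:
        x += spec.hum_amp_ecg_mV * np.sin(2 * np.pi * spec.hum_freq * t + rng.uniform(0, 2 * np.pi))
    # snap ground truth to the sample grid (template peaks sit on samples)
    truth = RRSeries(np.round(beat_times * spec.fs) / spec.fs)
    return x, truth


def _draw_kss(state: str, rng: np.random.Generator) -> int:
    return int(rng.integers(1, 6)) if state == "N" else int(rng.integers(6, 10))


def generate_dataset(spec: SimulationSpec = SimulationSpec(),
                     config: PipelineConfig | None = None,
                     trim: bool = True) -> tuple[list[LabeledSegment], list[dict]]:
    """Generate the full labelled cohort plus a ground-truth manifest.

    Returns trimmed :class:`LabeledSegment` objects (central part of each
    acquisition, per the pipeline's edge-trim rule) and one manifest entry
    per segment recording every generator parameter, for parameter-recovery
    tests.  Byte-identical for a fixed ``spec.seed``.
    """
    cfg = config or DEFAULT_CONFIG.with_(fs=spec.fs)
    ss = np.random.SeedSequence(spec.seed)
    segments: list[LabeledSegment] = []
    manifest: list[dict] = []
    n_n, n_y = spec.segments_per_state
    for si in range(spec.n_subjects):
        subj_rng = np.random.default_rng(ss.spawn(1)[0])
        subj_id = f"S{si + 1:02d}"
        rr_offset = float(subj_rng.normal(0.0, spec.subject_rr_sd))
        states = ["N"] * n_n + ["Y"] * n_y
        for gi, state in enumerate(states):
            rng = np.random.default_rng(ss.spawn(1)[0])
            eeg = simulate_eeg(state, spec, rng, config=cfg)
            p = spec.ecg_params(state)
            ecg, truth = simulate_ecg(state, spec, rng, rr_mean=p.rr_mean + rr_offset)
            kss = _draw_kss(state, rng)
            rec = Recording(subject_id=subj_id, eeg=eeg, ecg=ecg, fs=spec.fs, kss=kss)
            if trim:
                seg = trim_and_label(rec, config=cfg)
            else:
                seg = LabeledSegment(recording=rec, label=state)
            segments.append(seg)
            manifest.append({
                "subject_id": subj_id, "segment": gi, "state": state, "kss": kss,
                "shares": spec.shares(state), "rr_mean": p.rr_mean + rr_offset,
                "rmssd_target_ms": p.rmssd, "lf_hf_target": p.lf_hf,
                "r_peak_times": truth.r_peak_times.tolist(),
            })
    return segments, manifest
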