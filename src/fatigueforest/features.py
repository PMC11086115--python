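"""The 25 fatigue features: EEG band statistics and ECG heart-rate variability.

EEG features (numbers 1-20, each computed delta->gamma on the band-filtered
series): integrated Welch band power (PSD), differential entropy
``DE = 1/2 log2(2 pi e var)``, kurtosis (non-excess, Gaussian -> 3) and
skewness.  ECG features (21-25): mean heart rate (bpm), RMSSD (ms) and the
VLF-normalised LF/HF spectral indices of the R-R tachogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal as sps, stats

from .config import BandDefinition, BAND_NAMES, DEFAULT_BANDS, PipelineConfig, DEFAULT_CONFIG

#: Canonical ordering of the 25 features (EEG 1-20, ECG 21-25).
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{band}" for stat in ("psd", "de", "ks", "sk") for band in BAND_NAMES
) + ("hr", "rmssd", "lf_norm", "hf_norm", "lf_hf")

EEG_FEATURES = FEATURE_NAMES[:20]
ECG_FEATURES = FEATURE_NAMES[20:]

#: HRV spectral band edges (Hz): VLF below 0.04, LF, HF, total power to 0.4.
VLF_EDGE, LF_BAND, HF_BAND = 0.04, (0.04, 0.15), (0.15, 0.4)

#: Minimum inter-beat interval (refractory period) and longest credible beat, s.
RR_MIN, RR_MAX = 0.25, 3.0


class DetectionError(RuntimeError):
    """R-peak detection failed (no usable QRS complexes)."""


@dataclass(frozen=True)
class WelchSpec:
    """Welch periodogram settings: Hamming-windowed 2 s segments, 50% overlap."""

    nperseg: int = 500
    overlap: float = 0.5
    window: str = "hamming"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must lie in [0, 1)")
        if self.nperseg < 8:
            raise ValueError("nperseg too small")

    @property
    def noverlap(self) -> int:
        return int(self.nperseg * self.overlap)


DEFAULT_WELCH = WelchSpec()


def welch_psd(x: np.ndarray, fs: float, spec: WelchSpec = DEFAULT_WELCH):
    """Averaged-periodogram power spectral density (one-sided, units^2/Hz)."""
    x = np.asarray(x, dtype=float)
    if x.size < spec.nperseg:
        raise ValueError(f"signal of {x.size} samples shorter than nperseg={spec.nperseg}")
    f, p = sps.welch(x, fs=fs, window=spec.window, nperseg=spec.nperseg,
                     noverlap=spec.noverlap, detrend=False)
    return f, p


def band_power(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Integrated power over [lo, hi) from a PSD sampled on frequency grid f."""
    if f.size < 2:
        raise ValueError("PSD grid too short")
    df = f[1] - f[0]
    mask = (f >= lo) & (f < hi)
    return float(np.sum(p[mask]) * df)


def differential_entropy(x: np.ndarray) -> float:
    """Gaussian differential entropy in bits, ``1/2 log2(2 pi e var(x))``."""
    var = float(np.var(x))
    if var <= 0:
        raise ValueError("differential entropy undefined for a constant signal")
    return 0.5 * np.log2(2.0 * np.pi * np.e * var)


def eeg_features(bands: dict[str, np.ndarray], fs: float,
                 spec: WelchSpec = DEFAULT_WELCH,
                 band_defs: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> dict[str, float]:
    """The 20 EEG features on band-filtered series, ordered psd/de/ks/sk x delta->gamma."""
    edges = {b.name: (b.lo, b.hi) for b in band_defs}
    out: dict[str, float] = {}
    psds = {}
    for name in BAND_NAMES:
        x = bands[name]
        nper = min(spec.nperseg, x.size)
        f, p = welch_psd(x, fs, WelchSpec(nperseg=nper, overlap=spec.overlap,
                                          window=spec.window))
        psds[name] = band_power(f, p, *edges[name])
    for name in BAND_NAMES:
        out[f"psd_{name}"] = psds[name]
    for name in BAND_NAMES:
        out[f"de_{name}"] = differential_entropy(bands[name])
    for name in BAND_NAMES:
        out[f"ks_{name}"] = float(stats.kurtosis(bands[name], fisher=False))
    for name in BAND_NAMES:
        out[f"sk_{name}"] = float(stats.skew(bands[name]))
    return out


@dataclass
class RRSeries:
    """Detected R-peak times (s) and the successive inter-beat intervals."""

    r_peak_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.r_peak_times, dtype=float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("R-peak times must be strictly increasing")
        self.r_peak_times = t

    @property
    def rr_intervals(self) -> np.ndarray:
        """Inter-beat intervals in seconds."""
        return np.diff(self.r_peak_times)

    @property
    def span(self) -> float:
        return float(self.r_peak_times[-1] - self.r_peak_times[0]) if self.r_peak_times.size else 0.0

    def restrict(self, t0: float, t1: float) -> "RRSeries":
        """Peaks within the half-open window [t0, t1)."""
        t = self.r_peak_times
        return RRSeries(t[(t >= t0) & (t < t1)])


def detect_r_peaks(ecg: np.ndarray, fs: float) -> RRSeries:
    """Pan-Tompkins-style QRS detection.

    Band-pass 5-15 Hz, differentiate, square, integrate over a 150 ms moving
    window, threshold adaptively and refine each detection to the local ECG
    maximum.  A 250 ms refractory period separates accepted peaks.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < int(2 * fs):
        raise ValueError("need at least 2 s of ECG for peak detection")
    if np.ptp(ecg) == 0:
        raise DetectionError("flat signal: no QRS complexes")
    sos = sps.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp)
    sq = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(RR_MIN * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    # filter transients corrupt the signal edges
    edge = int(round(0.25 * fs))
    cand = cand[(cand >= edge) & (cand < ecg.size - edge)]
    if cand.size == 0:
        raise DetectionError("no candidate peaks")
    # adaptive threshold: a fraction of the typical strong-beat energy
    strong = np.percentile(mwi[cand], 90)
    thr = 0.2 * strong
    cand = cand[mwi[cand] >= thr]
    if cand.size == 0:
        raise DetectionError("all candidates below threshold")

    # refine to the true R maximum on the input trace (+-100 ms)
    half = int(round(0.100 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(ecg.size, c + half + 1)
        peaks.append(lo + int(np.argmax(ecg[lo:hi])))
    peaks = np.unique(peaks)
    # enforce the refractory period after refinement
    kept = [int(peaks[0])]
    for p in peaks[1:]:
        if p - kept[-1] >= refractory:
            kept.append(int(p))
        elif ecg[p] > ecg[kept[-1]]:
            kept[-1] = int(p)
    return RRSeries(np.asarray(kept, dtype=float) / fs)


def time_domain_hrv(rr: RRSeries) -> tuple[float, float]:
    """Mean heart rate (bpm) and RMSSD (ms) from the inter-beat intervals."""
    intervals = rr.rr_intervals
    if intervals.size < 2:
        raise ValueError("need at least 2 R-R intervals for time-domain HRV")
    hr = float(np.mean(60.0 / intervals))
    diffs = np.diff(intervals)
    rmssd = float(np.sqrt(np.mean(diffs ** 2))) * 1000.0
    return hr, rmssd


def freq_domain_hrv(rr: RRSeries, resample_fs: float = 4.0,
                    nperseg: int = 64) -> tuple[float, float, float]:
    """VLF-normalised LF and HF power and their ratio.

    The unevenly sampled tachogram (RR value at the time of the closing beat)
    is cubic-interpolated onto a uniform ``resample_fs`` grid, linearly
    detrended, and Welch-estimated.  ``lf_norm = LF/(TP-VLF)``,
    ``hf_norm = HF/(TP-VLF)``, ``lf_hf = lf_norm/hf_norm``.
    """
    t = rr.r_peak_times
    intervals = rr.rr_intervals
    if intervals.size < 4:
        raise ValueError("need at least 4 R-R intervals for spectral HRV")
    if rr.span < 20.0:
        raise ValueError("R-R series must span at least 20 s for spectral HRV")
    tt = t[1:]
    kind = "cubic" if intervals.size >= 4 else "linear"
    f_interp = interpolate.interp1d(tt, intervals, kind=kind, assume_sorted=True)
    grid = np.arange(tt[0], tt[-1], 1.0 / resample_fs)
    tach = sps.detrend(f_interp(grid), type="linear")
    nper = min(nperseg, tach.size)
    f, p = sps.welch(tach, fs=resample_fs, window="hamming", nperseg=nper,
                     noverlap=nper // 2, detrend=False)
    vlf = band_power(f, p, 0.0, VLF_EDGE)
    lf = band_power(f, p, *LF_BAND)
    hf = band_power(f, p, *HF_BAND)
    tp = band_power(f, p, 0.0, HF_BAND[1])
    denom = tp - vlf
    if denom <= 0 or hf <= 0:
        raise ValueError("degenerate tachogram spectrum (no power above VLF)")
    lf_norm = lf / denom
    hf_norm = hf / denom
    return float(lf_norm), float(hf_norm), float(lf_norm / hf_norm)


def ecg_features(rr: RRSeries) -> dict[str, float]:
    """The 5 HRV features, ordered hr, rmssd, lf_norm, hf_norm, lf_hf."""
    hr, rmssd = time_domain_hrv(rr)
    lf_norm, hf_norm, lf_hf = freq_domain_hrv(rr)
    return {"hr": hr, "rmssd": rmssd, "lf_norm": lf_norm,
            "hf_norm": hf_norm, "lf_hf": lf_hf}


def extract_all(segment, config: PipelineConfig = DEFAULT_CONFIG,
                welch: WelchSpec = DEFAULT_WELCH) -> np.ndarray:
    """Full 25-feature vector for a labelled segment (EEG 1-20, ECG 21-25).

    The segment is denoised internally: EEG through wavelet soft thresholding
    plus the mains notch, ECG through the Kalman/high-pass/notch stage used
    for R-peak detection.
    """
    from .eeg import band_decompose, denoise_eeg
    from .ecg import clean_ecg_for_peaks

    rec = segment.recording
    cfg = config if config.fs == rec.fs else config.with_(fs=rec.fs)
    eeg_clean = denoise_eeg(rec.eeg, cfg)
    bands = band_decompose(eeg_clean, cfg.bands, fs=rec.fs)
    rr = detect_r_peaks(clean_ecg_for_peaks(rec.ecg, cfg), rec.fs)
    feats = eeg_features(bands, rec.fs, welch, cfg.bands)
    feats.update(ecg_features(rr))
    vec = np.array([feats[name] for name in FEATURE_NAMES], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(vec))]
        raise ValueError(f"non-finite features: {bad}")
    return vec
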