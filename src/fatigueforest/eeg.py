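"""EEG denoising (wavelet soft thresholding) and rhythm-band decomposition."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .config import BandDefinition, DEFAULT_BANDS, PipelineConfig, DEFAULT_CONFIG, validate_bands
from .ecg import notch_filter, wavelet_decompose, wavelet_reconstruct

__all__ = [
    "compute_soft_threshold",
    "soft_threshold",
    "dwt_soft_denoise",
    "band_decompose",
    "denoise_eeg",
]


def compute_soft_threshold(coeffs: list[np.ndarray]) -> float:
    """Threshold = half the standard deviation of the finest detail coefficients.

    ``coeffs`` is a ``pywt.wavedec`` pyramid ``[cA_J, cD_J, ..., cD_1]``; the
    finest level is the last entry.
    """
    if len(coeffs) < 2:
        raise ValueError("decomposition must contain at least one detail level")
    finest = np.asarray(coeffs[-1], dtype=float)
    if finest.size == 0:
        raise ValueError("empty coefficient array")
    return float(np.std(finest)) / 2.0


def soft_threshold(c: np.ndarray, lam: float) -> np.ndarray:
    """Soft shrinkage ``sign(c) * max(|c| - lam, 0)``."""
    if lam < 0:
        raise ValueError("threshold must be non-negative")
    c = np.asarray(c, dtype=float)
    return np.sign(c) * np.maximum(np.abs(c) - lam, 0.0)


def dwt_soft_denoise(x: np.ndarray, wavelet: str = "db4", level: int = 5) -> np.ndarray:
    """Wavelet denoising: soft-threshold every detail level, keep the approximation.

    The threshold is estimated once from the finest detail level (where the
    coefficients are noise-dominated) and applied uniformly to all detail
    levels; approximation coefficients carry the slow EEG content and are
    never shrunk.
    """
    x = np.asarray(x, dtype=float)
    coeffs = wavelet_decompose(x, wavelet, level)
    lam = compute_soft_threshold(coeffs)
    coeffs = [coeffs[0]] + [soft_threshold(c, lam) for c in coeffs[1:]]
    return wavelet_reconstruct(coeffs, wavelet, x.size)


def band_decompose(x: np.ndarray, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                   fs: float = 250.0, order: int = 4) -> dict[str, np.ndarray]:
    """Split a clean EEG trace into one zero-phase band-passed series per rhythm.

    Returns ``{band name: series}`` with every series the same length as the
    input.  Band edges are the canonical delta/theta/alpha/beta/gamma ranges.
    """
    x = np.asarray(x, dtype=float)
    validate_bands(tuple(bands), fs)
    out: dict[str, np.ndarray] = {}
    for b in bands:
        sos = sps.butter(order, [b.lo, b.hi], btype="bandpass", fs=fs, output="sos")
        out[b.name] = sps.sosfiltfilt(sos, x)
    return out


def denoise_eeg(x: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Full EEG chain: DWT soft-threshold denoising then the 49-51 Hz notch."""
    y = dwt_soft_denoise(x, wavelet=config.wavelet, level=config.dwt_level)
    y = notch_filter(y, f0=config.notch_f0, band=config.notch_band,
                     order=config.notch_order, fs=config.fs)
    return y
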