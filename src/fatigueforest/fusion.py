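"""Sliding-window multimodal feature-matrix construction.

A labelled segment is swept by half-open windows [ti, ti+W), ti = t0 + i*S
(defaults W = 30 s, S = 1 s), and the selected features are extracted per
window; rows stacked chronologically form the fusion matrix fed to the
classifier.  Every row inherits the segment's label, the only labelling
granularity available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG
from .ecg import clean_ecg_for_peaks
from .eeg import band_decompose, denoise_eeg
from .features import (DEFAULT_WELCH, ECG_FEATURES, FEATURE_NAMES, WelchSpec,
                       detect_r_peaks, ecg_features, eeg_features)
from .io import LabeledSegment

logger = logging.getLogger(__name__)


def sliding_windows(t0: float, t_end: float, W: float, S: float) -> list[tuple[float, float]]:
    """Half-open windows [ti, ti+W), ti = t0 + i*S, fully inside [t0, t_end]."""
    if W <= 0 or S <= 0:
        raise ValueError("window and step must be positive")
    span = t_end - t0
    if span < W:
        raise ValueError(f"window of {W} s exceeds the {span} s span")
    count = int(np.floor((span - W) / S + 1e-9)) + 1
    return [(t0 + i * S, t0 + i * S + W) for i in range(count)]


def resolve_selection(selection) -> list[str]:
    """Normalise a feature selection (names or 0-based indices) to names."""
    if selection is None:
        return list(FEATURE_NAMES)
    names = []
    for s in selection:
        if isinstance(s, str):
            if s not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {s!r}")
            names.append(s)
        else:
            names.append(FEATURE_NAMES[int(s)])
    return names


@dataclass
class FusionMatrix:
    """Windows x selected-features matrix for one segment."""

    X: np.ndarray
    columns: list[str]
    t_start: np.ndarray
    label: str
    subject_id: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "t_start", self.t_start)
        df["label"] = self.label
        df["subject_id"] = self.subject_id
        return df


def build_feature_matrix(segment: LabeledSegment, selection=None,
                         config: PipelineConfig = DEFAULT_CONFIG,
                         welch: WelchSpec = DEFAULT_WELCH,
                         max_dropped: float = 0.10) -> FusionMatrix:
    """Sliding-window fusion matrix of one preprocessed segment.

    Denoising and R-peak detection run once on the whole segment; each window
    then slices the band-filtered EEG series and the detected beat series.
    Windows whose feature extraction fails are dropped with a warning; more
    than ``max_dropped`` of them is an error.
    """
    rec = segment.recording
    cfg = config if config.fs == rec.fs else config.with_(fs=rec.fs)
    names = resolve_selection(selection)

    eeg_clean = denoise_eeg(rec.eeg, cfg)
    bands = band_decompose(eeg_clean, cfg.bands, fs=rec.fs)
    rr = detect_r_peaks(clean_ecg_for_peaks(rec.ecg, cfg), rec.fs)

    ecg_set = set(ECG_FEATURES)
    need_eeg = any(n not in ecg_set for n in names)
    need_ecg = any(n in ecg_set for n in names)

    windows = sliding_windows(0.0, rec.duration, cfg.window, cfg.step)
    rows, starts, dropped = [], [], 0
    for (w0, w1) in windows:
        i0, i1 = int(round(w0 * rec.fs)), int(round(w1 * rec.fs))
        try:
            feats: dict[str, float] = {}
            if need_eeg:
                feats.update(eeg_features({b: s[i0:i1] for b, s in bands.items()},
                                          rec.fs, welch, cfg.bands))
            if need_ecg:
                feats.update(ecg_features(rr.restrict(w0, w1)))
            row = [feats[n] for n in names]
            if not np.all(np.isfinite(row)):
                raise ValueError("non-finite feature")
        except Exception as exc:
            dropped += 1
            logger.warning("window [%.1f, %.1f) dropped: %s", w0, w1, exc)
            continue
        rows.append(row)
        starts.append(w0 + rec.start_time)
    if dropped > max_dropped * len(windows):
        raise RuntimeError(
            f"{dropped}/{len(windows)} windows failed feature extraction")
    return FusionMatrix(X=np.asarray(rows, dtype=float), columns=names,
                        t_start=np.asarray(starts), label=segment.label,
                        subject_id=rec.subject_id)


def dataset_feature_table(segments: list[LabeledSegment], selection=None,
                          config: PipelineConfig = DEFAULT_CONFIG,
                          welch: WelchSpec = DEFAULT_WELCH) -> pd.DataFrame:
    """Stack per-segment fusion matrices into one labelled feature table."""
    frames = [build_feature_matrix(seg, selection, config, welch).to_frame()
              for seg in segments]
    return pd.concat(frames, ignore_index=True)
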