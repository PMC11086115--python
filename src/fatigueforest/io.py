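"""Recording data model, CSV/EDF I/O, edge trimming, labelling and splitting.

A :class:`Recording` holds one dual-channel (EEG microvolts + ECG millivolts)
segment.  On disk the native format is a plain CSV with columns
``time,eeg_uV,ecg_mV`` plus an optional JSON sidecar
``{subject_id, kss, start_time}``; EDF files are read-only via :mod:`mne`.

Labelling follows the Karolinska Sleepiness Scale convention used throughout
the package: KSS >= 6 is fatigued (``"Y"``), KSS <= 5 is not (``"N"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .config import PipelineConfig, DEFAULT_CONFIG

KSS_FATIGUE_THRESHOLD = 6


class ParseError(ValueError):
    """Malformed on-disk recording."""


class SamplingError(ValueError):
    """Non-uniform or unusable time base."""


@dataclass
class Recording:
    """One raw dual-channel physiological segment.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the segment was acquired from.
    eeg, ecg : ndarray
        Equal-length sample arrays, EEG in microvolts and ECG in millivolts.
    fs : float
        Sampling rate in Hz (250 in the study protocol).
    start_time : float
        Offset of the first sample in seconds.
    kss : int or None
        Karolinska Sleepiness Scale self-report (1-9), if available.
    """

    subject_id: str
    eeg: np.ndarray
    ecg: np.ndarray
    fs: float
    start_time: float = 0.0
    kss: int | None = None

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.ecg = np.asarray(self.ecg, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.eeg.shape != self.ecg.shape or self.eeg.ndim != 1:
            raise ValueError("eeg and ecg must be 1-D arrays of equal length")
        if self.kss is not None and not (1 <= int(self.kss) <= 9):
            raise ValueError(f"kss must lie in [1, 9], got {self.kss}")

    @property
    def n_samples(self) -> int:
        return self.eeg.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class LabeledSegment:
    """A recording together with its binary fatigue label ``"N"``/``"Y"``."""

    recording: Recording
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("N", "Y"):
            raise ValueError(f"label must be 'N' or 'Y', got {self.label!r}")
        kss = self.recording.kss
        if kss is not None:
            expect = "Y" if kss >= KSS_FATIGUE_THRESHOLD else "N"
            if self.label != expect:
                raise ValueError(f"label {self.label!r} inconsistent with KSS {kss}")


def label_from_kss(kss: int) -> str:
    """Map a KSS score (1-9) to the binary fatigue label."""
    if not (1 <= kss <= 9):
        raise ValueError(f"kss must lie in [1, 9], got {kss}")
    return "Y" if kss >= KSS_FATIGUE_THRESHOLD else "N"


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV (+ JSON sidecar) at full float precision."""
    path = Path(path)
    df = pd.DataFrame(
        {"time": rec.times, "eeg_uV": rec.eeg, "ecg_mV": rec.ecg}
    )
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {"subject_id": rec.subject_id, "kss": rec.kss, "start_time": rec.start_time}
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def _read_csv_recording(path: Path) -> Recording:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"time", "eeg_uV", "ecg_mV"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in required:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ParseError(f"{path}: missing value in column {col!r} at row {int(bad[0])}")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise SamplingError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SamplingError(f"{path}: time column not strictly increasing")
    dt_med = float(np.median(dt))
    if np.max(np.abs(dt - dt_med)) > 0.01 * dt_med:
        raise SamplingError(f"{path}: non-uniform sampling (>1% timestamp jitter)")
    fs = 1.0 / dt_med

    sidecar_path = path.with_suffix(".json")
    subject_id, kss, start_time = path.stem, None, float(t[0])
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        subject_id = meta.get("subject_id", subject_id)
        kss = meta.get("kss")
        start_time = float(meta.get("start_time", start_time))
    return Recording(
        subject_id=subject_id,
        eeg=df["eeg_uV"].to_numpy(dtype=float),
        ecg=df["ecg_mV"].to_numpy(dtype=float),
        fs=fs,
        start_time=start_time,
        kss=kss,
    )


def _read_edf_recording(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if len(raw.ch_names) < 2:
        raise ParseError(f"{path}: EDF must contain at least 2 signals")
    data = raw.get_data()
    # first channel -> EEG (V -> uV), second -> ECG (V -> mV)
    return Recording(
        subject_id=path.stem,
        eeg=data[0] * 1e6,
        ecg=data[1] * 1e3,
        fs=float(raw.info["sfreq"]),
    )


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from CSV (native) or EDF.

    The format is inferred from the suffix unless given explicitly.  CSV
    sampling rate comes from the ``time`` column, which must be uniform to
    within 1% jitter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        return _read_csv_recording(path)
    if fmt == "edf":
        return _read_edf_recording(path)
    raise ValueError(f"unknown format {fmt!r}")


def trim_and_label(rec: Recording, kss: int | None = None,
                   config: PipelineConfig = DEFAULT_CONFIG) -> LabeledSegment:
    """Discard the unstable first/last ``trim_edges`` seconds and attach a label.

    A 5 min acquisition trimmed by 30 s at each end yields exactly the central
    4 min.  The KSS score may come from the recording itself or be supplied.
    """
    if kss is None:
        kss = rec.kss
    if kss is None:
        raise ValueError("no KSS score available for labelling")
    label = label_from_kss(int(kss))
    n_trim = int(round(config.trim_edges * rec.fs))
    min_dur = 2 * config.trim_edges + config.window
    if rec.duration < min_dur:
        raise ValueError(
            f"recording of {rec.duration:.1f} s too short: need >= {min_dur:.1f} s "
            f"(2x{config.trim_edges:.0f} s trim + {config.window:.0f} s window)"
        )
    sl = slice(n_trim, rec.n_samples - n_trim)
    trimmed = Recording(
        subject_id=rec.subject_id,
        eeg=rec.eeg[sl],
        ecg=rec.ecg[sl],
        fs=rec.fs,
        start_time=rec.start_time + config.trim_edges,
        kss=int(kss),
    )
    return LabeledSegment(recording=trimmed, label=label)


def split_dataset(X, y, seed: int, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)):
    """Stratified train/validation/test index split (default 60/20/20).

    Returns three disjoint integer index arrays covering ``range(len(y))``,
    with per-set sizes within 1 of the requested fractions and both classes
    present in every set.  Deterministic given ``seed``.
    """
    y = np.asarray(y)
    n = len(y)
    if X is not None and len(X) != n:
        raise ValueError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("cannot stratify a single-class dataset")
    if counts.min() < 5:
        raise ValueError("need >= 5 samples per class for a stratified 60/20/20 split")
    f_train, f_val, f_test = fractions
    n_test = int(round(f_test * n))
    n_val = int(round(f_val * n))
    idx = np.arange(n)
    idx_trainval, idx_test = train_test_split(
        idx, test_size=n_test, stratify=y, random_state=seed)
    idx_train, idx_val = train_test_split(
        idx_trainval, test_size=n_val, stratify=y[idx_trainval], random_state=seed)
    return np.sort(idx_train), np.sort(idx_val), np.sort(idx_test)
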