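"""Pipeline-wide configuration and the canonical EEG band plan.

All stages share one :class:`PipelineConfig`.  Defaults follow the study
protocol this package implements: 250 Hz dual-channel acquisition, 30 s
trimmed from each end of a 5 min segment, Butterworth high-pass at 0.5 Hz
(order 5), 49-51 Hz Butterworth band-stop (order 4), db4 wavelets at 5
decomposition levels, 30 s analysis windows stepped by 1 s, 5-fold CV and a
stratified 60/20/20 train/validation/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class BandDefinition:
    """One named EEG rhythm band with half-open frequency edges [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(f"band {self.name}: need 0 < lo < hi, got [{self.lo}, {self.hi})")


#: Canonical EEG rhythm bands (Hz): delta, theta, alpha, beta, gamma.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def validate_bands(bands: tuple[BandDefinition, ...], fs: float) -> None:
    """Check bands are ascending, non-overlapping and below Nyquist."""
    prev_hi = 0.0
    for b in bands:
        if b.lo < prev_hi:
            raise ValueError(f"bands overlap or are out of order at {b.name}")
        if b.hi > fs / 2:
            raise ValueError(f"band {b.name} upper edge {b.hi} Hz >= Nyquist {fs / 2} Hz")
        prev_hi = b.hi


@dataclass(frozen=True)
class PipelineConfig:
    fs: float = 250.0                     # sampling rate, Hz
    trim_edges: float = 30.0              # seconds discarded at each end
    hp_cutoff: float = 0.5                # baseline high-pass cutoff fc, Hz
    hp_order: int = 5
    notch_f0: float = 50.0                # mains interference centre, Hz
    notch_band: tuple[float, float] = (49.0, 51.0)
    notch_order: int = 4
    wavelet: str = "db4"
    dwt_level: int = 5                    # decomposition depth J
    window: float = 30.0                  # sliding-window length W, s
    step: float = 1.0                     # sliding-window step S, s
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    cv_folds: int = 5
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_cascade_rf_range: tuple[int, int] = (1, 10)
    n_tree_range: tuple[int, int] = (10, 300)
    bo_iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        validate_bands(self.bands, self.fs)

    def with_(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_CONFIG = PipelineConfig()
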