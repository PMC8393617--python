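"""EEG channel preprocessing: bandpass filtering, scaling, resampling.

The fixed pipeline order is bandpass -> min-max normalize -> resample ->
segment.  The bandpass (0.5-35 Hz Butterworth, order 4, applied
forward-backward so phase-A transients keep their shape) matches standard
sleep-EEG practice; normalization is per channel per recording so the
amplitude contrast between activation bursts and background survives.
Recordings sampled at 512 Hz are brought to a 64 Hz analysis rate so a
five-level dyadic decomposition lands on the 0-1 ... 16-32 Hz band ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = ["TimeSeries", "bandpass_filter", "minmax_normalize", "resample_to", "preprocess_channel"]

ANALYSIS_RATE = 64.0


@dataclass
class TimeSeries:
    """A single-channel EEG trace."""

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite samples in channel {self.label!r}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def bandpass_filter(
    x: TimeSeries, low: float = 0.5, high: float = 35.0, order: int = 4
) -> TimeSeries:
    """Zero-phase Butterworth bandpass (applied forward-backward)."""
    nyq = x.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"cutoffs ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq}"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=x.fs, output="sos")
    return replace(x, samples=signal.sosfiltfilt(sos, x.samples))


def minmax_normalize(x: TimeSeries) -> TimeSeries:
    """Rescale amplitudes to [0, 1]: ``(x - min) / (max - min)``."""
    lo, hi = x.samples.min(), x.samples.max()
    if hi == lo:
        raise ValueError(f"constant signal in channel {x.label!r}: zero range")
    return replace(x, samples=(x.samples - lo) / (hi - lo))


def resample_to(x: TimeSeries, fs_out: float = ANALYSIS_RATE) -> TimeSeries:
    """Polyphase anti-aliased resampling to ``fs_out`` (must not exceed fs)."""
    if fs_out > x.fs:
        raise ValueError(f"fs_out = {fs_out} exceeds input rate {x.fs}")
    if fs_out == x.fs:
        return x
    frac = Fraction(fs_out / x.fs).limit_denominator(1000)
    y = signal.resample_poly(x.samples, frac.numerator, frac.denominator)
    return replace(x, samples=y, fs=fs_out)


def preprocess_channel(
    x: TimeSeries,
    low: float = 0.5,
    high: float = 35.0,
    order: int = 4,
    fs_out: float = ANALYSIS_RATE,
) -> TimeSeries:
    """Full chain: bandpass -> normalize -> resample."""
    return resample_to(minmax_normalize(bandpass_filter(x, low, high, order)), fs_out)
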