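"""Synthetic sleep-EEG generator with CAP phase structure and ground truth.

Phase B (background) is band-limited 1/f^beta noise (0.5-35 Hz, unit RMS),
the stereotypical low-amplitude NREM background.  Phase A epochs carry the
same background plus a cerebral-activation transient: either a raised-
cosine-windowed delta-band (0.5-4 Hz) burst, or, with probability
``k_complex_prob``, a biphasic K-complex-like wave of about 0.8 s.  The
transient amplitude is ``(amp_ratio - 1)`` times the background RMS, so
``amp_ratio = 1`` degenerates to phases drawn from the identical law (the
null condition) and larger ratios give increasingly separable classes.
Two channels share half their background variance by default, emulating
the common cortical source behind the C4-A1 and F4-C4 derivations.

No claim of physiological realism is made beyond this amplitude/spectral
structure: there are no spindles, no stage architecture, no artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cap_rules import AnnotationEvent, EpochSet
from .preprocess import TimeSeries

__all__ = ["SynthParams", "generate_epoch_set", "generate_annotated_recording"]

CHANNEL_NAMES = ("C4-A1", "F4-C4")


@dataclass
class SynthParams:
    """Generator settings.

    amp_ratio is the ratio of total phase-A transient amplitude to the
    background RMS (>= 1); background_exponent is the spectral slope beta
    of the 1/f^beta background; channel_correlation is the shared-variance
    fraction between the two channels.
    """

    fs: float = 512.0
    epoch_len: float = 2.0
    n_epochs: int = 1000
    amp_ratio: float = 5.0
    background_exponent: float = 1.0
    k_complex_prob: float = 0.2
    channel_correlation: float = 0.5
    band: tuple[float, float] = (0.5, 35.0)
    delta_band: tuple[float, float] = (0.5, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amp_ratio < 1:
            raise ValueError("amp_ratio must be >= 1")
        if not 0 <= self.k_complex_prob <= 1:
            raise ValueError("k_complex_prob must be in [0, 1]")
        if not 0 <= self.channel_correlation <= 1:
            raise ValueError("channel_correlation must be in [0, 1]")


def _shaped_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band: tuple[float, float],
    beta: float,
) -> np.ndarray:
    """Gaussian noise with power spectral density f^-beta inside ``band``."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    gain = np.zeros(len(freqs))
    inband = (freqs >= band[0]) & (freqs <= band[1])
    gain[inband] = freqs[inband] ** (-beta / 2.0)
    x = np.fft.irfft(spec * gain, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _background_pair(
    rng: np.random.Generator, n: int, p: SynthParams
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-RMS backgrounds with shared-variance fraction rho."""
    rho = p.channel_correlation
    shared = _shaped_noise(rng, n, p.fs, p.band, p.background_exponent)
    out = []
    for _ in CHANNEL_NAMES:
        own = _shaped_noise(rng, n, p.fs, p.band, p.background_exponent)
        x = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own
        out.append(x / np.sqrt(np.mean(x**2)))
    return out[0], out[1]


def _delta_burst(rng: np.random.Generator, n: int, p: SynthParams) -> np.ndarray:
    """Raised-cosine-windowed delta-band burst with unit peak envelope RMS."""
    burst = _shaped_noise(rng, n, p.fs, p.delta_band, p.background_exponent)
    window = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))
    x = burst * window
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _k_complex(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Biphasic ~0.8 s transient (one slow cycle under a Hann envelope)."""
    dur = min(int(round(0.8 * fs)), n)
    t = np.arange(dur) / fs
    wave = np.sin(2.0 * np.pi * t / (dur / fs))
    wave *= 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(dur) / dur))
    start = rng.integers(0, n - dur + 1)
    x = np.zeros(n)
    x[start : start + dur] = wave
    rms = np.sqrt(np.mean(x**2))
    return x / rms


def _phase_a_transient(rng: np.random.Generator, n: int, p: SynthParams) -> np.ndarray:
    amp = p.amp_ratio - 1.0
    if amp == 0.0:
        return np.zeros(n)
    if rng.random() < p.k_complex_prob:
        return amp * _k_complex(rng, n, p.fs)
    return amp * _delta_burst(rng, n, p)


def generate_epoch_set(p: SynthParams, seed: int | None = None) -> EpochSet:
    """``n_epochs`` phase-A plus ``n_epochs`` phase-B two-channel epochs.

    Deterministic for a given seed (``p.seed`` unless overridden).
    """
    rng = np.random.default_rng(p.seed if seed is None else seed)
    n = int(round(p.epoch_len * p.fs))
    data = {ch: np.empty((2 * p.n_epochs, n)) for ch in CHANNEL_NAMES}
    labels = np.array(["A"] * p.n_epochs + ["B"] * p.n_epochs)
    for i, label in enumerate(labels):
        ch0, ch1 = _background_pair(rng, n, p)
        if label == "A":
            transient = _phase_a_transient(rng, n, p)
            ch0 = ch0 + transient
            ch1 = ch1 + transient
        data[CHANNEL_NAMES[0]][i] = ch0
        data[CHANNEL_NAMES[1]][i] = ch1
    return EpochSet(channels=data, labels=labels, epoch_len=p.epoch_len, fs=p.fs)


def generate_annotated_recording(
    p: SynthParams,
    layout: list[tuple[str, float]],
    seed: int | None = None,
) -> tuple[dict[str, TimeSeries], list[AnnotationEvent]]:
    """Continuous two-channel recording realizing a phase layout.

    ``layout`` is a list of ``(kind, duration_s)`` entries with kinds
    ``"A"`` (phase A, 2-60 s), ``"B"`` (intra-sequence background, 2-60 s)
    and ``"NC"`` (non-CAP gap, > 60 s).  A intervals carry phase-A texture;
    the returned annotations reproduce the layout's A events exactly, plus
    one NREM2 stage event spanning the whole recording.
    """
    for kind, dur in layout:
        if kind in ("A", "B") and not 2.0 <= dur <= 60.0:
            raise ValueError(f"{kind} duration {dur} s outside [2, 60] s")
        if kind == "NC" and dur <= 60.0:
            raise ValueError(f"non-CAP gap {dur} s must exceed 60 s")
        if kind not in ("A", "B", "NC"):
            raise ValueError(f"unknown layout kind {kind!r}")
    rng = np.random.default_rng(p.seed if seed is None else seed)
    total = sum(d for _, d in layout)
    n = int(round(total * p.fs))
    ch0, ch1 = _background_pair(rng, n, p)
    events: list[AnnotationEvent] = [
        AnnotationEvent(onset=0.0, duration=total, label="NREM2")
    ]
    t = 0.0
    for kind, dur in layout:
        if kind == "A":
            i0, i1 = int(round(t * p.fs)), int(round((t + dur) * p.fs))
            transient = _phase_a_transient(rng, i1 - i0, p)
            ch0[i0:i1] += transient
            ch1[i0:i1] += transient
            events.append(AnnotationEvent(onset=t, duration=dur, label="A"))
        t += dur
    channels = {
        CHANNEL_NAMES[0]: TimeSeries(samples=ch0, fs=p.fs, label=CHANNEL_NAMES[0]),
        CHANNEL_NAMES[1]: TimeSeries(samples=ch1, fs=p.fs, label=CHANNEL_NAMES[1]),
    }
    return channels, events
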