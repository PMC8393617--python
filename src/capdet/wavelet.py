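"""Dyadic wavelet analysis/synthesis with periodic boundary extension.

A ``levels``-deep decomposition of an epoch sampled at ``fs`` produces
``levels + 1`` subbands ordered ``[D1, ..., Dlevels, Alevels]``: detail
coefficients covering the dyadic halves ``(fs/4, fs/2), (fs/8, fs/4), ...``
and a final approximation covering ``(0, fs/2^(levels+1))``.  At the 64 Hz
analysis rate used for CAP feature extraction, five levels give the six
bands 16-32, 8-16, 4-8, 2-4, 1-2 and 0-1 Hz.

Periodic (circular) extension keeps the transform orthonormal, so subband
lengths are exactly ``N/2, N/4, ..., N/2^levels, N/2^levels`` and Parseval
holds: the subband energies sum to the input energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filterbank import WaveletFilterBank

__all__ = ["SubbandSet", "analyze", "synthesize", "subband_ranges"]


@dataclass
class SubbandSet:
    """Wavelet coefficients ``[D1..Dlevels, Alevels]`` of one or more epochs.

    Each entry of ``coeffs`` has the input's leading shape with the last
    axis halved per level; ``ranges`` holds the matching (low, high)
    frequency intervals in Hz.
    """

    coeffs: list[np.ndarray]
    ranges: list[tuple[float, float]]
    fs: float

    @property
    def levels(self) -> int:
        return len(self.coeffs) - 1

    def energies(self) -> np.ndarray:
        """Per-subband energy, summed over the last axis."""
        return np.array([np.sum(np.square(c), axis=-1) for c in self.coeffs])


def subband_ranges(fs: float, levels: int) -> list[tuple[float, float]]:
    """Frequency intervals for ``[D1..Dlevels, Alevels]`` by dyadic halving of [0, fs/2]."""
    edges = [fs / 2.0 / 2.0**j for j in range(levels + 1)]
    out = [(edges[j + 1], edges[j]) for j in range(levels)]
    out.append((0.0, edges[levels]))
    return out


def _analysis_indices(n_samples: int, L: int) -> np.ndarray:
    n = np.arange(n_samples // 2)
    return (2 * n[:, None] + np.arange(L)[None, :]) % n_samples


def _analyze_level(x: np.ndarray, fb: WaveletFilterBank) -> tuple[np.ndarray, np.ndarray]:
    idx = _analysis_indices(x.shape[-1], fb.L)
    windows = x[..., idx]
    return windows @ fb.h, windows @ fb.g


def analyze(x: np.ndarray, fb: WaveletFilterBank, fs: float = 64.0) -> SubbandSet:
    """Iterated two-channel decomposition of ``x`` (last axis = time).

    ``x.shape[-1]`` must be divisible by ``2**fb.levels``.  Works on a single
    epoch (1-D) or a batch (epochs stacked along leading axes).
    """
    x = np.asarray(x, dtype=float)
    step = 2**fb.levels
    if x.shape[-1] % step:
        raise ValueError(
            f"signal length {x.shape[-1]} not divisible by 2^levels = {step}"
        )
    details: list[np.ndarray] = []
    approx = x
    for _ in range(fb.levels):
        approx, d = _analyze_level(approx, fb)
        details.append(d)
    return SubbandSet(
        coeffs=details + [approx], ranges=subband_ranges(fs, fb.levels), fs=fs
    )


def _synthesize_level(
    a: np.ndarray, d: np.ndarray, fb: WaveletFilterBank
) -> np.ndarray:
    n_out = 2 * a.shape[-1]
    idx = _analysis_indices(n_out, fb.L)
    lead = a.shape[:-1]
    y = np.zeros(lead + (n_out,))
    contrib = a[..., :, None] * fb.h + d[..., :, None] * fb.g
    flat_y = y.reshape(-1, n_out)
    flat_c = contrib.reshape(-1, *idx.shape)
    for row in range(flat_y.shape[0]):
        np.add.at(flat_y[row], idx.ravel(), flat_c[row].ravel())
    return y


def synthesize(s: SubbandSet, fb: WaveletFilterBank) -> np.ndarray:
    """Inverse transform; exact (to rounding) for orthonormal banks."""
    if len(s.coeffs) != fb.levels + 1:
        raise ValueError(
            f"subband count {len(s.coeffs)} does not match levels={fb.levels}"
        )
    approx = s.coeffs[-1]
    for d in reversed(s.coeffs[:-1]):
        approx = _synthesize_level(approx, d, fb)
    return approx
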