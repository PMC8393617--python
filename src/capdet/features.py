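"""Subband wavelet-entropy and Hjorth features, and Kruskal-Wallis ranking.

Per channel, each epoch is decomposed into the six subbands
``[D1..D5, A5]`` and four scalars are computed per subband, in fixed order
``entropy, activity, mobility, complexity``:

* wavelet entropy ``E = -sum_i |c_i| log|c_i|`` (natural log, 0 log 0 = 0),
  evaluated on raw coefficient magnitudes; a normalized-probability variant
  (``p_i = |c_i| / sum|c_j|``) is available but off by default;
* Hjorth activity, the population variance of the coefficients;
* Hjorth mobility ``sigma(x') / sigma(x)`` with ``x'`` the first
  difference — a mean-frequency proxy;
* Hjorth complexity ``mobility(x') / mobility(x)`` — a bandwidth proxy.

Two channels x six subbands x four features give the 48-dimensional vector
used for CAP phase classification.  Feature names follow
``{channel}.{subband}.{feature}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .cap_rules import EpochSet
from .filterbank import WaveletFilterBank
from .wavelet import analyze

__all__ = [
    "FeatureMatrix",
    "wavelet_entropy",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "extract_epoch_features",
    "extract_features",
    "kruskal_wallis_rank",
]

FEATURE_NAMES = ["entropy", "activity", "mobility", "complexity"]


def subband_names(levels: int) -> list[str]:
    """``[D1..Dlevels, Alevels]`` labels matching :func:`capdet.wavelet.analyze`."""
    return [f"D{j}" for j in range(1, levels + 1)] + [f"A{levels}"]


def wavelet_entropy(c: np.ndarray, normalized: bool = False) -> float:
    """``-sum_i |c_i| log|c_i|`` over wavelet coefficient magnitudes.

    With ``normalized=True`` magnitudes are first scaled to sum to one
    (a Shannon entropy over the magnitude distribution).
    """
    mag = np.abs(np.asarray(c, dtype=float))
    if normalized:
        total = mag.sum()
        if total == 0:
            return 0.0
        mag = mag / total
    return float(-np.sum(_xlogx(mag)))


def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log(x[nz])
    return out


def hjorth_activity(x: np.ndarray) -> float:
    """Population variance of the signal."""
    return float(np.var(np.asarray(x, dtype=float)))


def hjorth_mobility(x: np.ndarray) -> float:
    """sigma(x')/sigma(x), first-difference derivative."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x)
    if sd == 0:
        raise ValueError("constant input: mobility undefined")
    return float(np.std(np.diff(x)) / sd)


def hjorth_complexity(x: np.ndarray) -> float:
    """mobility(x')/mobility(x); requires length >= 3."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("complexity needs at least 3 samples")
    return float(hjorth_mobility(np.diff(x)) / hjorth_mobility(x))


@dataclass
class FeatureMatrix:
    """Epochs x named features with phase labels."""

    values: np.ndarray
    names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != (len(self.labels), len(self.names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.labels)} labels x {len(self.names)} names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def n_features(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df["label"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(values=df.to_numpy(float), names=list(df.columns), labels=labels)


def _batch_features(coeffs: np.ndarray) -> np.ndarray:
    """entropy, activity, mobility, complexity along the last axis (batched).

    Degenerate (constant) inputs yield 0 mobility/complexity with a warning
    so downstream classifiers never see non-finite values.
    """
    mag = np.abs(coeffs)
    ent = -np.sum(_xlogx(mag), axis=-1)
    act = np.var(coeffs, axis=-1)
    sd0 = np.std(coeffs, axis=-1)
    d1 = np.diff(coeffs, axis=-1)
    sd1 = np.std(d1, axis=-1)
    sd2 = np.std(np.diff(d1, axis=-1), axis=-1)
    degenerate = (sd0 == 0) | (sd1 == 0)
    if np.any(degenerate):
        warnings.warn("constant subband: mobility/complexity recorded as 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        mob = np.where(sd0 > 0, sd1 / np.where(sd0 > 0, sd0, 1.0), 0.0)
        cpx = np.where(
            (sd1 > 0) & (sd0 > 0),
            (sd2 / np.where(sd1 > 0, sd1, 1.0)) / np.where(mob > 0, mob, 1.0),
            0.0,
        )
    return np.stack([ent, act, mob, cpx], axis=-1)


def _resample_batch(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if fs_in == fs_out:
        return x
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def extract_epoch_features(
    epoch: dict[str, np.ndarray],
    fb: WaveletFilterBank,
    fs: float = 64.0,
) -> tuple[np.ndarray, list[str]]:
    """Feature vector and names for a single epoch (channel -> samples)."""
    vec: list[float] = []
    names: list[str] = []
    for ch, samples in epoch.items():
        sb = analyze(np.asarray(samples, float), fb, fs=fs)
        for band_name, c in zip(subband_names(fb.levels), sb.coeffs):
            feats = _batch_features(c[None, :])[0]
            vec.extend(feats.tolist())
            names.extend(f"{ch}.{band_name}.{f}" for f in FEATURE_NAMES)
    return np.array(vec), names


def extract_features(
    epochs: EpochSet,
    fb: WaveletFilterBank,
    analysis_fs: float = 64.0,
) -> FeatureMatrix:
    """Features for every epoch of an :class:`EpochSet`.

    Epochs sampled faster than ``analysis_fs`` are resampled first so the
    five-level decomposition covers 0-32 Hz.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for ch, arr in epochs.channels.items():
        x = _resample_batch(arr, epochs.fs, analysis_fs)
        sb = analyze(x, fb, fs=analysis_fs)
        for band_name, c in zip(subband_names(fb.levels), sb.coeffs):
            blocks.append(_batch_features(c))
            names.extend(f"{ch}.{band_name}.{f}" for f in FEATURE_NAMES)
    values = np.concatenate(blocks, axis=-1)
    return FeatureMatrix(values=values, names=names, labels=epochs.labels.copy())


def kruskal_wallis_rank(fm: FeatureMatrix) -> pd.DataFrame:
    """Rank features by the Kruskal-Wallis H test between the two phases.

    Returns a frame with columns ``name, H, p_value, rank`` (rank 1 = most
    significant); ties in p are broken by descending H, then feature index.
    """
    classes = np.unique(fm.labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    groups = [fm.values[fm.labels == c] for c in classes]
    if min(len(g) for g in groups) < 2:
        raise ValueError("each class needs at least 2 epochs")
    H = np.empty(fm.n_features)
    p = np.empty(fm.n_features)
    for j in range(fm.n_features):
        a, b = groups[0][:, j], groups[1][:, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            H[j], p[j] = 0.0, 1.0
            continue
        H[j], p[j] = stats.kruskal(a, b)
    order = np.lexsort((np.arange(fm.n_features), -H, p))
    rank = np.empty(fm.n_features, dtype=int)
    rank[order] = np.arange(1, fm.n_features + 1)
    return pd.DataFrame({"name": fm.names, "H": H, "p_value": p, "rank": rank})
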