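"""Handcrafted temporal/spectral features and fusion with CNN features.

Nine interpretable statistics are computed per (single-channel) segment:
min, max, mean, variance, standard deviation and skewness in the time
domain, plus spectral centroid, spectral variance and spectral skewness
from the power spectral density.  Moments use the population (1/K)
normalization; skewness is standardized (third central moment / sigma^3),
zero by convention for a constant signal.  Spectral moments are
power-weighted moments of the frequency grid in Hz, so the centroid is a
physical frequency.

The fused representation concatenates the 9 handcrafted values with the
CNN's global-average-pool feature vector (512-wide for the full
architecture), each block z-scored with training-set statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram, welch

from .io import Segment

__all__ = [
    "HandcraftedFeatures",
    "SpectralEstimate",
    "FEATURE_NAMES",
    "temporal_features",
    "psd",
    "spectral_features",
    "handcrafted_features",
    "feature_matrix",
    "FusionScaler",
    "fuse",
]

#: column order of the feature matrix (matches the reporting convention)
FEATURE_NAMES = [
    "min", "max", "mean", "variance", "standard_deviation", "skewness",
    "spectral_centroid", "spectral_variance", "spectral_skewness",
]


@dataclass(frozen=True)
class HandcraftedFeatures:
    """The nine per-segment statistics, in volts / Hz units."""

    min: float
    max: float
    mean: float
    variance: float
    std: float
    skewness: float
    spectral_centroid: float
    spectral_variance: float
    spectral_skewness: float

    def as_array(self) -> np.ndarray:
        return np.array([
            self.min, self.max, self.mean, self.variance, self.std,
            self.skewness, self.spectral_centroid, self.spectral_variance,
            self.spectral_skewness,
        ])


@dataclass(frozen=True)
class SpectralEstimate:
    """A one-sided PSD on an ascending frequency grid in Hz."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.power < -1e-300):
            raise ValueError("power must be nonnegative")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly ascending")


def _as_1d(seg: Segment | np.ndarray) -> np.ndarray:
    if isinstance(seg, Segment):
        if seg.n_channels != 1:
            raise ValueError(
                f"features are computed on a single channel (got {seg.n_channels})"
            )
        return seg.samples[0]
    x = np.asarray(seg, dtype=float)
    return x.ravel()


def temporal_features(seg: Segment | np.ndarray) -> tuple[float, ...]:
    """(min, max, mean, variance, std, skewness) with 1/K moments."""
    x = _as_1d(seg)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    var = ((x - mu) ** 2).mean()
    std = np.sqrt(var)
    if std == 0:
        skew = 0.0
    else:
        skew = ((x - mu) ** 3).mean() / std**3
    return float(x.min()), float(x.max()), float(mu), float(var), float(std), float(skew)


def psd(
    seg: Segment | np.ndarray,
    sampling_rate: float | None = None,
    method: str = "periodogram",
) -> SpectralEstimate:
    """PSD of a single-channel segment (mean removed before estimation).

    ``periodogram`` (default) satisfies Parseval — the integrated density
    equals the signal variance; ``welch`` trades that exactness for
    variance reduction of the estimate.
    """
    x = _as_1d(seg)
    if sampling_rate is None:
        if isinstance(seg, Segment):
            sampling_rate = seg.sampling_rate
        else:
            raise ValueError("sampling_rate required for array input")
    if x.size < 16:
        raise ValueError("need at least 16 samples for a spectral estimate")
    if method == "periodogram":
        f, p = periodogram(x, fs=sampling_rate, detrend="constant")
    elif method == "welch":
        f, p = welch(x, fs=sampling_rate, detrend="constant",
                     nperseg=min(x.size, 1024))
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    return SpectralEstimate(frequencies=f[1:], power=np.maximum(p[1:], 0.0))


def spectral_features(estimate: SpectralEstimate) -> tuple[float, float, float]:
    """(centroid Hz, spectral variance Hz^2, spectral skewness).

    Power-weighted moments of the frequency grid; skewness is 0 by
    convention when the spectral variance vanishes (all power in one bin).
    """
    f, p = estimate.frequencies, estimate.power
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total spectral power; spectral moments undefined")
    centroid = float((f * p).sum() / total)
    var = float((((f - centroid) ** 2) * p).sum() / total)
    if var == 0:
        skew = 0.0
    else:
        sd = np.sqrt(var)
        skew = float(((((f - centroid) / sd) ** 3) * p).sum() / total)
    return centroid, var, skew


def handcrafted_features(
    seg: Segment | np.ndarray,
    sampling_rate: float | None = None,
    method: str = "periodogram",
) -> HandcraftedFeatures:
    """All nine features of one single-channel segment."""
    mn, mx, mu, var, std, skew = temporal_features(seg)
    cs, svar, sskew = spectral_features(psd(seg, sampling_rate, method))
    return HandcraftedFeatures(mn, mx, mu, var, std, skew, cs, svar, sskew)


def feature_matrix(
    segments, sampling_rate: float | None = None, method: str = "periodogram"
) -> np.ndarray:
    """(n_segments, 9) matrix in :data:`FEATURE_NAMES` column order."""
    return np.stack(
        [handcrafted_features(s, sampling_rate, method).as_array() for s in segments]
    )


class FusionScaler:
    """Z-scores the handcrafted and CNN blocks with training-set statistics.

    Fit on training data only; applying to held-out rows reuses the stored
    means/scales, so no test-fold information leaks into the scaling.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    @staticmethod
    def _concat(handcrafted: np.ndarray, cnn: np.ndarray) -> np.ndarray:
        h = np.atleast_2d(np.asarray(handcrafted, dtype=float))
        c = np.atleast_2d(np.asarray(cnn, dtype=float))
        if h.shape[0] != c.shape[0]:
            raise ValueError("handcrafted and CNN blocks disagree on row count")
        return np.hstack([h, c])

    def fit(self, handcrafted: np.ndarray, cnn: np.ndarray) -> "FusionScaler":
        x = self._concat(handcrafted, cnn)
        self.mean_ = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, handcrafted: np.ndarray, cnn: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("FusionScaler must be fit before transform")
        return (self._concat(handcrafted, cnn) - self.mean_) / self.scale_

    def fit_transform(self, handcrafted: np.ndarray, cnn: np.ndarray) -> np.ndarray:
        return self.fit(handcrafted, cnn).transform(handcrafted, cnn)


def fuse(
    handcrafted: np.ndarray,
    cnn_vectors: np.ndarray,
    scaler: FusionScaler | None = None,
) -> tuple[np.ndarray, FusionScaler]:
    """Concatenate standardized [handcrafted | CNN] blocks.

    With the default 512-wide CNN block the fused vector has length
    9 + 512 = 521.  Pass a previously fitted ``scaler`` to transform
    held-out rows with training statistics; otherwise one is fit here.
    """
    if scaler is None:
        scaler = FusionScaler()
        fused = scaler.fit_transform(handcrafted, cnn_vectors)
    else:
        fused = scaler.transform(handcrafted, cnn_vectors)
    return fused, scaler
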