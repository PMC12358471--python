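"""Channel ranking and surrogate-channel construction.

High-dimensional multichannel EEG is collapsed to a single *surrogate
channel* before feature extraction.  Channels are first ranked on two
criteria — pooled signal variance (higher = more brain activity) and a
signal-quality index (fraction of spectral power inside the physiological
0.5–40 Hz band) — and the top-ranked subset is kept.  The surrogate is then
either the pointwise channel mean (an SNR-raising averaging filter) or, by
default, the projection onto the leading common-spatial-patterns (CSP)
filter: the linear channel combination maximizing preictal variance
relative to interictal variance.

CSP here solves the generalized eigenproblem of the pencil
``(C_pre, C_pre + C_inter)`` on trace-normalized average class covariances,
so eigenvalues lie in [0, 1] and measure the relative preictal variance
captured by each filter.  CSP is class-supervised: fit it on training folds
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
from scipy.signal import periodogram

from .io import Segment

__all__ = [
    "ChannelRanking",
    "SpatialFilterModel",
    "channel_variance",
    "signal_quality_index",
    "select_channels",
    "average_surrogate",
    "fit_csp",
    "apply_surrogate",
]


@dataclass
class ChannelRanking:
    """Outcome of variance/SQI channel selection."""

    variance_per_channel: np.ndarray  # volts^2
    sqi_per_channel: np.ndarray       # in [0, 1]
    combined_rank: np.ndarray         # rank sum, smaller = better
    selected_indices: list[int]       # ordered best-first

    def __post_init__(self) -> None:
        n = len(self.variance_per_channel)
        if not (len(self.sqi_per_channel) == len(self.combined_rank) == n):
            raise ValueError("per-channel arrays must have equal length")
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected_indices must be distinct")


@dataclass
class SpatialFilterModel:
    """Fitted CSP model: class covariances, filters (rows) and eigenvalues."""

    class_covariances: tuple[np.ndarray, np.ndarray]  # (preictal, interictal)
    filters: np.ndarray           # (n_filters, n_channels), rows are filters
    eigenvalues: np.ndarray       # in [0, 1], descending
    selected_filter_index: int = 0

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]


def _stack(segments: Sequence[Segment] | np.ndarray) -> np.ndarray:
    """(n_segments, channels, time) array from segments or an array."""
    if isinstance(segments, np.ndarray):
        arr = segments
        if arr.ndim == 2:
            arr = arr[None]
        return arr
    return np.stack([s.samples for s in segments])


def channel_variance(segments: Sequence[Segment] | np.ndarray) -> np.ndarray:
    """Pooled population variance per channel, ``(1/K) sum (x - mu)^2``.

    The mean and the normalization pool over every sample of every provided
    segment (K = total sample count per channel).
    """
    arr = _stack(segments)
    if arr.shape[0] * arr.shape[2] < 2:
        raise ValueError("need at least 2 samples per channel")
    flat = arr.transpose(1, 0, 2).reshape(arr.shape[1], -1)
    return flat.var(axis=1)  # numpy default ddof=0 = population variance


def signal_quality_index(
    channel_signal: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (0.5, 40.0),
) -> float:
    """In-band power fraction from the periodogram, in [0, 1].

    A proxy for recording quality: 1 means all spectral power lies inside
    the physiological band, 0 means none does.  Alternative scorers can be
    passed to :func:`select_channels`.
    """
    x = np.asarray(channel_signal, dtype=float).ravel()
    if x.size < 2 * sampling_rate:
        raise ValueError("need at least 2 s of signal for a stable SQI")
    f, p = periodogram(x, fs=sampling_rate, detrend="constant")
    total = p.sum()
    if total <= 0:
        return 0.0
    in_band = p[(f >= band[0]) & (f <= band[1])].sum()
    return float(in_band / total)


def select_channels(
    segments: Sequence[Segment] | np.ndarray,
    sampling_rate: float | None = None,
    n_select: int = 5,
    band: tuple[float, float] = (0.5, 40.0),
    sqi_fn: Callable[[np.ndarray, float], float] | None = None,
) -> ChannelRanking:
    """Rank channels by variance-rank + SQI-rank and keep the best ``n_select``.

    Each criterion is ranked separately (0 = best, descending value order);
    the combined score is the sum of the two ranks and ties break toward the
    lower channel index.
    """
    arr = _stack(segments)
    if sampling_rate is None:
        if not isinstance(segments, np.ndarray) and len(segments):
            sampling_rate = segments[0].sampling_rate
        else:
            raise ValueError("sampling_rate required for array input")
    n_channels = arr.shape[1]
    if not 1 <= n_select <= n_channels:
        raise ValueError(f"n_select must be in [1, {n_channels}]")

    variances = channel_variance(arr)
    flat = arr.transpose(1, 0, 2).reshape(n_channels, -1)
    if sqi_fn is None:
        sqis = np.array(
            [signal_quality_index(flat[c], sampling_rate, band) for c in range(n_channels)]
        )
    else:
        sqis = np.array([float(sqi_fn(flat[c], sampling_rate)) for c in range(n_channels)])

    def ranks_desc(values: np.ndarray) -> np.ndarray:
        # rank 0 = largest value; ties broken by lower channel index
        order = np.lexsort((np.arange(len(values)), -values))
        r = np.empty(len(values), dtype=int)
        r[order] = np.arange(len(values))
        return r

    combined = ranks_desc(variances) + ranks_desc(sqis)
    order = np.lexsort((np.arange(n_channels), combined))
    return ChannelRanking(
        variance_per_channel=variances,
        sqi_per_channel=sqis,
        combined_rank=combined,
        selected_indices=[int(i) for i in order[:n_select]],
    )


def average_surrogate(seg: Segment | np.ndarray) -> Segment | np.ndarray:
    """Pointwise mean across channels: the averaging-filter surrogate."""
    if isinstance(seg, Segment):
        return seg.with_samples(seg.samples.mean(axis=0, keepdims=True))
    arr = np.atleast_2d(np.asarray(seg, dtype=float))
    return arr.mean(axis=0, keepdims=True)


def _avg_normalized_cov(trials: np.ndarray) -> np.ndarray:
    """Average trace-normalized covariance over (n_trials, ch, time)."""
    covs = np.einsum("nct,ndt->ncd", trials, trials)
    traces = np.einsum("ncc->n", covs)
    return (covs / traces[:, None, None]).mean(axis=0)


def fit_csp(
    preictal_segments: Sequence[Segment] | np.ndarray,
    interictal_segments: Sequence[Segment] | np.ndarray,
) -> SpatialFilterModel:
    """Fit CSP filters separating preictal from interictal variance.

    Per-trial covariances are trace-normalized before averaging (so
    high-amplitude trials do not dominate), then the filters solve
    ``C_pre w = lambda (C_pre + C_inter) w``.  Eigenvalues (descending) are
    the fraction of composite variance each filter assigns to the preictal
    class; the leading filter is the "optimal spatial filter" used for the
    surrogate channel.
    """
    pre = _stack(preictal_segments)
    inter = _stack(interictal_segments)
    if pre.shape[0] == 0 or inter.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    if pre.shape[1] != inter.shape[1]:
        raise ValueError("classes must share the channel set")
    c_pre = _avg_normalized_cov(pre)
    c_inter = _avg_normalized_cov(inter)
    composite = c_pre + c_inter
    # regularize a singular composite covariance
    eps = 1e-8 * np.trace(composite) / composite.shape[0]
    try:
        np.linalg.cholesky(composite)
    except np.linalg.LinAlgError:
        warnings.warn(f"singular composite covariance; adding {eps:.3g} * I")
        composite = composite + eps * np.eye(composite.shape[0])
    eigvals, eigvecs = scipy.linalg.eigh(c_pre, composite)
    order = np.argsort(eigvals)[::-1]
    return SpatialFilterModel(
        class_covariances=(c_pre, c_inter),
        filters=eigvecs[:, order].T,
        eigenvalues=eigvals[order],
        selected_filter_index=0,
    )


def apply_surrogate(
    model: SpatialFilterModel, seg: Segment | np.ndarray
) -> Segment | np.ndarray:
    """Project a multichannel segment onto the selected CSP filter."""
    w = model.filters[model.selected_filter_index]
    if isinstance(seg, Segment):
        if seg.n_channels != model.n_channels:
            raise ValueError(
                f"segment has {seg.n_channels} channels, model expects "
                f"{model.n_channels}"
            )
        return seg.with_samples((w @ seg.samples)[None, :])
    arr = np.atleast_2d(np.asarray(seg, dtype=float))
    if arr.shape[0] != model.n_channels:
        raise ValueError("channel count mismatch")
    return (w @ arr)[None, :]
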