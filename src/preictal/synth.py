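"""Seeded synthetic multichannel EEG with controllable preictal/interictal contrast.

The generator exists so that the whole prediction pipeline — denoising,
channel selection, CSP surrogate construction, feature extraction and the
stacked classifier — is testable end-to-end without downloading clinical
data.  Each channel is a sum of band-limited oscillations (delta/theta/
alpha/beta) plus 1/f "pink" background noise, the standard additive model
of scalp-EEG background activity.

The two classes differ in two controlled ways, mirroring the empirical
contrast between preictal and interictal scalp EEG feature tables:

* preictal segments have **smaller broadband amplitude** (variance of order
  1e-9 V^2 vs 1e-8 V^2 interictal), and
* preictal oscillatory power is **shifted toward the slow bands**, lowering
  the spectral centroid (roughly 4-6 Hz vs 12-20 Hz).

``class_separation`` scales that contrast geometrically: 0 makes the two
classes draws from the *same* distribution (the null used for chance-level
checks), 1 gives the default contrast, larger values exaggerate it.
Identical ``(config, schedule, seed)`` always yields bit-identical output.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .io import INTERICTAL, PREICTAL, Recording, Segment, SeizureAnnotation

__all__ = [
    "SynthConfig",
    "StateSchedule",
    "generate_recording",
    "generate_labeled_segments",
    "inject_artifacts",
    "DEFAULT_BAND_POWERS",
]

#: per-class oscillatory bands: name -> (center frequency Hz, amplitude volts).
#: Amplitudes are at the ~1e-5..1e-4 V scale of scalp EEG; the preictal entry
#: is the *full-shift* (class_separation = 1) target.
DEFAULT_BAND_POWERS: dict[str, dict[str, tuple[float, float]]] = {
    INTERICTAL: {
        "delta": (2.0, 1.75e-5),
        "theta": (6.0, 3.15e-5),
        "alpha": (10.0, 5.6e-5),
        "beta": (21.0, 7.0e-5),
    },
    PREICTAL: {
        "delta": (2.0, 2.0e-5),
        "theta": (6.0, 1.4e-5),
        "alpha": (10.0, 0.7e-5),
        "beta": (21.0, 0.24e-5),
    },
}

#: artifact kinds understood by :func:`inject_artifacts`
ARTIFACT_KINDS = ("blink", "muscle", "line")

PREICTAL_HORIZON_S = 1800.0  # preictal = the 30 min before onset


@dataclass
class SynthConfig:
    """Parameters of the synthetic EEG model (see module docstring)."""

    sampling_rate: float = 256.0
    n_channels: int = 23
    session_duration: float = 3600.0
    window_s: float = 15.0
    band_powers: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_BAND_POWERS)
    )
    #: 1/f noise amplitude, as a fraction of the class's oscillatory RMS
    pink_noise_scale: float = 0.7
    #: 0 = classes identical; 1 = default preictal/interictal contrast
    class_separation: float = 1.0
    #: per-band amplitude jitter (log-normal sigma) giving segment-to-segment
    #: variability within a class
    amplitude_jitter: float = 0.25
    artifact_rates: dict[str, float] = field(default_factory=dict)  # events/min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        for cls in (INTERICTAL, PREICTAL):
            if cls not in self.band_powers:
                raise ValueError(f"band_powers must define class {cls!r}")
        for kind in self.artifact_rates:
            if kind not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind {kind!r}")

    def class_bands(self, label: str) -> dict[str, tuple[float, float]]:
        """Band parameters for ``label`` at the configured class separation.

        Interictal bands are the baseline; preictal bands are interpolated
        geometrically in amplitude (linearly in center frequency) between
        the baseline and the full-shift preictal entry, so that
        ``class_separation = 0`` reproduces the interictal distribution
        exactly.
        """
        base = self.band_powers[INTERICTAL]
        if label == INTERICTAL:
            return dict(base)
        s = self.class_separation
        out = {}
        for name, (f_base, a_base) in base.items():
            f_pre, a_pre = self.band_powers[PREICTAL].get(name, (f_base, a_base))
            out[name] = (
                f_base + s * (f_pre - f_base),
                a_base * (a_pre / a_base) ** s,
            )
        return out


@dataclass
class StateSchedule:
    """Session layout: session boundaries and seizure intervals, in seconds."""

    session_boundaries: list[tuple[float, float]]
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s0, s1 in self.session_boundaries:
            if not s0 < s1:
                raise ValueError(f"bad session boundary [{s0}, {s1}]")
        prev_end = -math.inf
        for on, off in self.seizure_intervals:
            if not on < off:
                raise ValueError(f"bad seizure interval [{on}, {off}]")
            if on < prev_end:
                raise ValueError("seizure intervals must be sorted, non-overlapping")
            prev_end = off
            if not any(s0 <= on and off <= s1 for s0, s1 in self.session_boundaries):
                raise ValueError(
                    f"seizure [{on}, {off}] not contained in any session"
                )


# ---------------------------------------------------------------------------
# signal synthesis primitives
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    nonzero = f > 0
    scale[nonzero] = 1.0 / np.sqrt(f[nonzero])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _synth_block(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    n_channels: int,
    bands: dict[str, tuple[float, float]],
    noise_amp: float,
    jitter: float,
    t0: float = 0.0,
) -> np.ndarray:
    """One contiguous block of multichannel signal from a class distribution."""
    t = t0 + np.arange(n_samples) / fs
    out = np.zeros((n_channels, n_samples))
    for c in range(n_channels):
        for f_hz, amp in bands.values():
            a = amp * rng.lognormal(0.0, jitter)
            phase = rng.uniform(0, 2 * np.pi)
            out[c] += a * np.sin(2 * np.pi * f_hz * t + phase)
        if noise_amp > 0:
            out[c] += noise_amp * rng.lognormal(0.0, jitter) * _pink_noise(rng, n_samples)
    return out


def _noise_amp(config: SynthConfig, bands: dict[str, tuple[float, float]]) -> float:
    osc_rms = math.sqrt(sum(a * a / 2 for _, a in bands.values()))
    return config.pink_noise_scale * osc_rms


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_recording(
    config: SynthConfig,
    schedule: StateSchedule,
    subject_id: str = "synth",
    session_id: str = "s01",
) -> Recording:
    """Synthesize one continuous recording following a seizure schedule.

    Samples within the 30 minutes before a scheduled onset are drawn from
    the preictal distribution; everything else (including the ictal spans
    themselves, whose waveform morphology is not modeled) from the
    interictal distribution.  The block structure is aligned to the
    configured window length so that segment-level amplitude jitter is
    independent across windows.
    """
    fs = config.sampling_rate
    duration = max(s1 for _, s1 in schedule.session_boundaries)
    if duration > config.session_duration + 1e-9:
        raise ValueError(
            f"schedule extends to {duration:g} s, beyond the configured "
            f"session_duration {config.session_duration:g} s"
        )
    duration = config.session_duration
    n = int(round(duration * fs))
    rng = np.random.default_rng(config.seed)

    preictal_spans = [
        (max(0.0, on - PREICTAL_HORIZON_S), on) for on, _ in schedule.seizure_intervals
    ]

    def state_at(t: float) -> str:
        for a, b in schedule.seizure_intervals:
            if a <= t < b:
                return INTERICTAL  # ictal morphology not modeled
        for a, b in preictal_spans:
            if a <= t < b:
                return PREICTAL
        return INTERICTAL

    samples = np.empty((config.n_channels, n))
    block = int(round(config.window_s * fs))
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        label = state_at(i0 / fs)
        bands = config.class_bands(label)
        samples[:, i0:i1] = _synth_block(
            rng, i1 - i0, fs, config.n_channels, bands,
            _noise_amp(config, bands), config.amplitude_jitter, t0=i0 / fs,
        )
    annotations = [
        SeizureAnnotation(on, off, source="synthetic")
        for on, off in schedule.seizure_intervals
    ]
    rec = Recording(
        samples=samples,
        sampling_rate=fs,
        channel_names=[f"SYN{c:02d}" for c in range(config.n_channels)],
        subject_id=subject_id,
        session_id=session_id,
        annotations=annotations,
    )
    if config.artifact_rates:
        rec = inject_artifacts(
            rec,
            kinds=set(config.artifact_rates),
            rate=config.artifact_rates,
            seed=config.seed + 1,
        )
    return rec


def generate_labeled_segments(
    config: SynthConfig, n_per_class: int, window_s: float | None = None
) -> list[Segment]:
    """Draw ``n_per_class`` labeled segments per class, preictal first.

    Segments are drawn directly from the two class distributions (no
    surrounding session), which is what the classifier-level tests need.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    window_s = config.window_s if window_s is None else window_s
    fs = config.sampling_rate
    n = int(round(window_s * fs))
    rng = np.random.default_rng(config.seed)
    segments: list[Segment] = []
    for label in (PREICTAL, INTERICTAL):
        bands = config.class_bands(label)
        noise = _noise_amp(config, bands)
        for i in range(n_per_class):
            samples = _synth_block(
                rng, n, fs, config.n_channels, bands, noise,
                config.amplitude_jitter,
            )
            segments.append(
                Segment(
                    samples=samples,
                    sampling_rate=fs,
                    start_time=i * window_s,
                    label=label,
                    subject_id="synth",
                    session_id=f"synth-{label}",
                )
            )
    return segments


def inject_artifacts(
    recording: Recording,
    kinds: set[str] | frozenset[str],
    rate: float | dict[str, float],
    seed: int = 0,
) -> Recording:
    """Return a copy of ``recording`` with artifact events added.

    Supported kinds: ``blink`` (slow frontal transient, power below 2 Hz),
    ``muscle`` (high-frequency EMG burst above ~25 Hz), ``line`` (50 Hz
    mains tone burst).  ``rate`` is in events per minute, either one number
    for all kinds or a per-kind mapping.  The input recording is unchanged.
    """
    unknown = set(kinds) - set(ARTIFACT_KINDS)
    if unknown:
        raise ValueError(f"unknown artifact kinds {sorted(unknown)}")
    rates = {k: (rate[k] if isinstance(rate, dict) else float(rate)) for k in kinds}
    out = copy.deepcopy(recording)
    fs = recording.sampling_rate
    n = recording.n_samples
    minutes = recording.duration / 60.0
    rng = np.random.default_rng(seed)
    scale = float(np.std(recording.samples)) or 1e-5

    for kind in sorted(rates):
        n_events = rng.poisson(rates[kind] * minutes)
        for _ in range(n_events):
            t0 = rng.uniform(0, recording.duration)
            i0 = int(t0 * fs)
            if kind == "blink":
                width = 0.2  # s
                half = int(3 * width * fs)
                idx = np.arange(max(0, i0 - half), min(n, i0 + half))
                wave = 4 * scale * np.exp(-(((idx / fs) - t0) / width) ** 2)
                weights = rng.uniform(0.3, 1.0, recording.n_channels)
                out.samples[:, idx] += weights[:, None] * wave[None, :]
            elif kind == "muscle":
                dur = int(0.5 * fs)
                idx = np.arange(i0, min(n, i0 + dur))
                burst = rng.standard_normal(idx.size)
                # keep only the high-frequency half of the spectrum
                spec = np.fft.rfft(burst)
                f = np.fft.rfftfreq(idx.size, 1 / fs)
                spec[f < 25.0] = 0.0
                burst = np.fft.irfft(spec, idx.size)
                sd = burst.std() or 1.0
                ch = rng.integers(recording.n_channels)
                out.samples[ch, idx] += 3 * scale * burst / sd
            elif kind == "line":
                dur = int(2.0 * fs)
                idx = np.arange(i0, min(n, i0 + dur))
                tone = np.sin(2 * np.pi * 50.0 * idx / fs)
                out.samples[:, idx] += 2 * scale * tone[None, :]
    return out
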