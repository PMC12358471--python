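"""Recording/Segment data model, EDF I/O and CHB-MIT-style annotation parsing.

Scalp EEG arrives as multichannel EDF files (16-bit European Data Format,
the container used by the CHB-MIT corpus) accompanied by plain-text
"summary" files in which clinical experts list seizure start/end times per
session.  This module provides the in-memory containers used by every
downstream stage — :class:`Recording`, :class:`SeizureAnnotation` and
:class:`Segment` — together with readers and a minimal EDF writer.

Conventions: time is in seconds from session start, windows are half-open
``[start, end)``, amplitudes are volts.
"""

from __future__ import annotations

import re
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SeizureAnnotation",
    "Segment",
    "read_edf",
    "write_edf",
    "read_chbmit_summary",
    "slice_recording",
    "write_segment_manifest",
    "read_segment_manifest",
]

#: labels a Segment may carry; set only by the labeling operation
PREICTAL = "preictal"
INTERICTAL = "interictal"
UNLABELED = "unlabeled"


@dataclass(frozen=True)
class SeizureAnnotation:
    """A single expert-annotated seizure interval, seconds from session start."""

    onset: float
    offset: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.onset < self.offset:
            raise ValueError(
                f"invalid seizure interval [{self.onset}, {self.offset}]: "
                "need 0 <= onset < offset"
            )


@dataclass
class Recording:
    """A multichannel EEG session.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` float array in volts.
    sampling_rate
        Uniform sampling rate in Hz (all channels share it).
    channel_names
        Unique channel labels, one per row of ``samples``.
    annotations
        Seizure intervals in seconds from the start of this recording.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    subject_id: str = ""
    session_id: str = ""
    annotations: list[SeizureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("one channel name per channel required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        for ann in self.annotations:
            if ann.offset > self.duration + 1e-9:
                raise ValueError(
                    f"annotation [{ann.onset}, {ann.offset}] exceeds session "
                    f"duration {self.duration:g} s"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class Segment:
    """A fixed-length window cut from a recording.

    ``label`` is one of ``preictal`` / ``interictal`` / ``unlabeled`` and is
    assigned only by :func:`preictal.preprocess.label_segments`.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float
    label: str = UNLABELED
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.label not in (PREICTAL, INTERICTAL, UNLABELED):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "Segment":
        """Copy of this segment carrying new sample data (same provenance)."""
        return replace(self, samples=samples)


# ---------------------------------------------------------------------------
# EDF reading / writing
# ---------------------------------------------------------------------------

_EDF_HDR = struct.Struct("<8s80s80s8s8s8s44s8s8s4s")


def _read_edf_signal_headers(path: Path) -> tuple[list[str], list[int]]:
    """Parse just the per-signal EDF header fields we validate on."""
    with open(path, "rb") as f:
        fixed = f.read(256)
        if len(fixed) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            n_signals = int(fixed[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF header (signal count)") from exc
        labels_raw = f.read(16 * n_signals)
        if len(labels_raw) < 16 * n_signals:
            raise ValueError(f"{path}: truncated EDF signal headers")
        labels = [
            labels_raw[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip()
            for i in range(n_signals)
        ]
        # skip transducer(80) dim(8) pmin(8) pmax(8) dmin(8) dmax(8) prefilter(80)
        f.seek((80 + 8 + 8 + 8 + 8 + 8 + 80) * n_signals, 1)
        spr_raw = f.read(8 * n_signals)
        samples_per_record = [
            int(spr_raw[i * 8 : (i + 1) * 8].decode("ascii").strip())
            for i in range(n_signals)
        ]
    return labels, samples_per_record


def read_edf(path: str | Path, subject_id: str = "", session_id: str = "") -> Recording:
    """Read an EDF file into a :class:`Recording` at its native rate.

    The per-signal headers are validated first: duplicate channel labels and
    mixed per-channel sampling rates are rejected (all downstream math
    assumes one uniform rate).  Sample decoding is delegated to
    :func:`mne.io.read_raw_edf`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    labels, spr = _read_edf_signal_headers(path)
    data_labels = [l for l in labels if not l.upper().startswith("EDF ANNOTATION")]
    if len(set(data_labels)) != len(data_labels):
        dupes = sorted({l for l in data_labels if data_labels.count(l) > 1})
        raise ValueError(f"{path}: duplicate channel labels {dupes}")
    data_spr = [
        s for l, s in zip(labels, spr) if not l.upper().startswith("EDF ANNOTATION")
    ]
    if len(set(data_spr)) > 1:
        raise ValueError(
            f"{path}: mixed per-channel sampling rates {sorted(set(data_spr))} "
            "are not supported"
        )

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if not session_id:
        session_id = path.stem
    return Recording(
        samples=raw.get_data(),
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=subject_id,
        session_id=session_id,
    )


def write_edf(path: str | Path, recording: Recording) -> None:
    """Write a recording as a plain 16-bit EDF file.

    One data record per second, so the recording must span an integer number
    of seconds at an integer sampling rate.  Physical units are microvolts;
    amplitudes survive the round trip within one 16-bit quantization step of
    the per-channel physical range.
    """
    fs = recording.sampling_rate
    if fs != int(fs):
        raise ValueError("write_edf requires an integer sampling rate")
    fs = int(fs)
    n_ch, n = recording.samples.shape
    if n % fs != 0:
        raise ValueError(
            "write_edf requires a whole number of seconds "
            f"({n} samples at {fs} Hz)"
        )
    n_rec = n // fs
    uv = recording.samples * 1e6
    # symmetric-ish physical range per channel, floor 1 uV to avoid zero span
    pmins = np.minimum(uv.min(axis=1), -1.0)
    pmaxs = np.maximum(uv.max(axis=1), 1.0)

    def ascii_field(values: Sequence, width: int) -> bytes:
        out = b""
        for v in values:
            b = str(v).encode("ascii")[:width]
            out += b.ljust(width)
        return out

    hdr = b"0".ljust(8)
    hdr += str(recording.subject_id or "X").encode()[:80].ljust(80)
    hdr += str(recording.session_id or "X").encode()[:80].ljust(80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(256 + 256 * n_ch).encode().ljust(8)
    hdr += b"".ljust(44)
    hdr += str(n_rec).encode().ljust(8)
    hdr += b"1".ljust(8)
    hdr += str(n_ch).encode().ljust(4)
    hdr += ascii_field(recording.channel_names, 16)
    hdr += ascii_field([""] * n_ch, 80)
    hdr += ascii_field(["uV"] * n_ch, 8)
    hdr += ascii_field([f"{v:.6g}" for v in pmins], 8)
    hdr += ascii_field([f"{v:.6g}" for v in pmaxs], 8)
    hdr += ascii_field([-32768] * n_ch, 8)
    hdr += ascii_field([32767] * n_ch, 8)
    hdr += ascii_field([""] * n_ch, 80)
    hdr += ascii_field([fs] * n_ch, 8)
    hdr += ascii_field([""] * n_ch, 32)

    # re-read the ASCII physical limits so the stored gain matches the header
    pmins_h = np.array([float(f"{v:.6g}") for v in pmins])
    pmaxs_h = np.array([float(f"{v:.6g}") for v in pmaxs])
    gains = (pmaxs_h - pmins_h) / 65535.0
    dig = np.empty((n_ch, n), dtype="<i2")
    for c in range(n_ch):
        dig[c] = np.clip(
            np.round((uv[c] - pmins_h[c]) / gains[c] - 32768.0), -32768, 32767
        ).astype("<i2")
    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                f.write(dig[c, r * fs : (r + 1) * fs].tobytes())


# ---------------------------------------------------------------------------
# CHB-MIT summary annotation dialect
# ---------------------------------------------------------------------------

_FILE_RE = re.compile(r"^File Name:\s*(\S+)", re.M)
_NSEIZ_RE = re.compile(r"^Number of Seizures in File:\s*(\d+)", re.M)
_START_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.]+)\s*sec", re.M)
_END_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([\d.]+)\s*sec", re.M)


def read_chbmit_summary(text: str) -> dict[str, list[SeizureAnnotation]]:
    """Parse a CHB-MIT-style ``*-summary.txt`` into annotations per file.

    The dialect is line-oriented: each session block names the EDF file
    (``File Name:``), declares ``Number of Seizures in File:`` and, for each
    seizure, ``Seizure [n] Start Time: <s> seconds`` / ``Seizure [n] End
    Time: <s> seconds``.  Files declaring zero seizures map to empty lists.

    Raises
    ------
    ValueError
        If a declared seizure has ``end <= start`` or a block declares more
        seizures than it lists times for.
    """
    out: dict[str, list[SeizureAnnotation]] = {}
    matches = list(_FILE_RE.finditer(text))
    if not matches:
        warnings.warn("summary text contains no 'File Name:' blocks; nothing parsed")
        return out
    for i, m in enumerate(matches):
        block = text[m.start() : matches[i + 1].start() if i + 1 < len(matches) else None]
        fname = m.group(1)
        nseiz_m = _NSEIZ_RE.search(block)
        if nseiz_m is None:
            warnings.warn(f"{fname}: missing 'Number of Seizures in File:'; skipped")
            continue
        n_declared = int(nseiz_m.group(1))
        starts = [float(s) for s in _START_RE.findall(block)]
        ends = [float(s) for s in _END_RE.findall(block)]
        if len(starts) != n_declared or len(ends) != n_declared:
            raise ValueError(
                f"{fname}: declares {n_declared} seizures but lists "
                f"{len(starts)} start / {len(ends)} end times"
            )
        anns = []
        for s, e in zip(starts, ends):
            if s >= e:
                raise ValueError(f"{fname}: seizure start {s} >= end {e}")
            anns.append(SeizureAnnotation(onset=s, offset=e, source=fname))
        out[fname] = anns
    return out


def slice_recording(recording: Recording, start_s: float, end_s: float) -> Recording:
    """Time slice ``[start_s, end_s)`` with annotations re-based and clipped."""
    if not (0 <= start_s < end_s <= recording.duration + 1e-9):
        raise ValueError(
            f"slice [{start_s}, {end_s}] outside recording "
            f"[0, {recording.duration:g}]"
        )
    fs = recording.sampling_rate
    i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
    anns = []
    for a in recording.annotations:
        on, off = max(a.onset, start_s), min(a.offset, end_s)
        if on < off:
            anns.append(SeizureAnnotation(on - start_s, off - start_s, a.source))
    return Recording(
        samples=recording.samples[:, i0:i1].copy(),
        sampling_rate=fs,
        channel_names=list(recording.channel_names),
        subject_id=recording.subject_id,
        session_id=recording.session_id,
        annotations=anns,
    )


# ---------------------------------------------------------------------------
# Segment manifests (delimited text)
# ---------------------------------------------------------------------------

def write_segment_manifest(path: str | Path, segments: Sequence[Segment]) -> None:
    """Write segment provenance + labels as TSV (subject, session, start, label)."""
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in segments],
            "session_id": [s.session_id for s in segments],
            "start_time": [s.start_time for s in segments],
            "label": [s.label for s in segments],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_segment_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
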