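"""Disk formats: mono PCM WAV recordings and apnea annotation tracks.

Annotations are comma-separated text with an ``onset_s,offset_s`` header,
one row per apnea event, in seconds on a 0.5-s grid — the resolution at
which overnight recordings are scored.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

ALLOWED_RATES = (16000, 8000, 4000, 2000, 1000)
EVENT_GRID_S = 0.5
MIN_EVENT_S = 10.0


@dataclass
class AudioRecording:
    """A mono audio track with its patient identity.

    Amplitudes are floats in [-1, 1]; ``sample_rate`` is in Hz.
    """

    patient_id: str
    sample_rate: int
    samples: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(f"expected mono samples, got {self.samples.ndim} axes")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite amplitudes in recording")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True, order=True)
class ApneaEvent:
    """One scored apnea episode, [onset_s, offset_s) in seconds on a 0.5-s grid."""

    onset_s: float
    offset_s: float

    def __post_init__(self):
        if self.offset_s <= self.onset_s:
            raise ValueError(f"offset {self.offset_s} must exceed onset {self.onset_s}")
        for value in (self.onset_s, self.offset_s):
            if abs(value / EVENT_GRID_S - round(value / EVENT_GRID_S)) > 1e-6:
                raise ValueError(f"{value} s is not on the {EVENT_GRID_S} s grid")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def validate_events(events: list[ApneaEvent], warn_short: bool = True) -> list[ApneaEvent]:
    """Sort and check non-overlap; warn on events shorter than the 10-s minimum."""
    events = sorted(events)
    for prev, cur in zip(events, events[1:]):
        if cur.onset_s < prev.offset_s:
            raise ValueError(
                f"overlapping events: ({prev.onset_s}, {prev.offset_s}) and "
                f"({cur.onset_s}, {cur.offset_s})"
            )
    if warn_short:
        for ev in events:
            if ev.duration_s < MIN_EVENT_S:
                warnings.warn(
                    f"event ({ev.onset_s}, {ev.offset_s}) shorter than {MIN_EVENT_S} s",
                    stacklevel=2,
                )
    return events


def load_recording(path: str | os.PathLike) -> AudioRecording:
    """Read a mono PCM WAV file; amplitudes are rescaled to [-1, 1]."""
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"unreadable WAV header in {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(f"expected mono audio, got {data.shape[1]} channels in {path}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype} in {path}")
    patient_id = os.path.splitext(os.path.basename(path))[0]
    return AudioRecording(patient_id=patient_id, sample_rate=int(rate), samples=samples)


def store_recording(recording: AudioRecording, path: str | os.PathLike) -> None:
    """Write a recording as 16-bit PCM mono WAV. Out-of-range amplitudes are an error."""
    peak = np.max(np.abs(recording.samples)) if len(recording.samples) else 0.0
    if peak > 1.0:
        raise ValueError(f"amplitude {peak:.4f} outside [-1, 1]; refusing to clip")
    pcm = np.clip(np.round(recording.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, recording.sample_rate, pcm)


def load_events(path: str | os.PathLike) -> list[ApneaEvent]:
    """Read an annotation CSV (columns onset_s, offset_s) into a sorted event list."""
    table = pd.read_csv(path)
    missing = {"onset_s", "offset_s"} - set(table.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    events = []
    for onset, offset in zip(table["onset_s"], table["offset_s"]):
        onset = round(float(onset) / EVENT_GRID_S) * EVENT_GRID_S \
            if abs(float(onset) / EVENT_GRID_S - round(float(onset) / EVENT_GRID_S)) <= 1e-6 \
            else float(onset)
        offset = round(float(offset) / EVENT_GRID_S) * EVENT_GRID_S \
            if abs(float(offset) / EVENT_GRID_S - round(float(offset) / EVENT_GRID_S)) <= 1e-6 \
            else float(offset)
        events.append(ApneaEvent(onset_s=onset, offset_s=offset))
    return validate_events(events)


def store_events(events: list[ApneaEvent], path: str | os.PathLike) -> None:
    """Write events as annotation CSV; inverse of :func:`load_events`."""
    events = validate_events(events, warn_short=False)
    table = pd.DataFrame(
        {"onset_s": [e.onset_s for e in events], "offset_s": [e.offset_s for e in events]}
    )
    table.to_csv(path, index=False)
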