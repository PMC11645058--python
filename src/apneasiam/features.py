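"""Windowing, labeling, and spectrogram feature extraction.

Recordings are cut into contiguous, non-overlapping 6-s windows.  A window
is positive (*apnea*) only when a single annotated event covers it
entirely; partial coverage counts as *non-apnea*.  Features are either a
32-band Mel power spectrogram at 16 kHz — with variants that keep only the
lowest 8/12/18/25 bands, emulating analyses of 1/2/4/8 kHz signals by
band truncation rather than re-analysis — or a linear-frequency magnitude
STFT of the signal genuinely resampled to 1 kHz.

Both analyses use a 2048-sample window with a 256-sample hop and centred
frames (the signal is reflect-padded by half a window on each side), so a
6-s window yields 1 + floor(n / hop) frames: 376 at 16 kHz, 24 at 1 kHz.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .dataio import ApneaEvent, AudioRecording

WINDOW_S = 6.0
LOG_FLOOR = 1e-10
MEL_BAND_OPTIONS = (8, 12, 18, 25, 32)


@dataclass(frozen=True)
class LabeledWindow:
    patient_id: str
    start_s: float
    end_s: float
    label: str  # "apnea" | "non_apnea"

    def __post_init__(self):
        if abs((self.end_s - self.start_s) - WINDOW_S) > 1e-9:
            raise ValueError("windows must span exactly 6 s")
        if self.label not in ("apnea", "non_apnea"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class FeatureConfig:
    """Spectrogram recipe; see the module docstring for conventions."""

    feature_type: str = "mel"  # "mel" | "stft"
    n_mels_total: int = 32
    n_bands_kept: int = 32
    win_length: int = 2048
    hop_length: int = 256
    analysis_sr: int = 16000
    center_padding: bool = True
    log_scale: bool = True
    standardize: bool = True

    def __post_init__(self):
        if self.feature_type not in ("mel", "stft"):
            raise ValueError(f"unknown feature_type {self.feature_type!r}")
        if self.feature_type == "mel":
            if self.n_bands_kept not in MEL_BAND_OPTIONS:
                raise ValueError(f"n_bands_kept must be one of {MEL_BAND_OPTIONS}")
            if self.n_bands_kept > self.n_mels_total:
                raise ValueError("n_bands_kept cannot exceed n_mels_total")
        if self.win_length <= self.hop_length:
            raise ValueError("win_length must exceed hop_length")

    @property
    def n_bands(self) -> int:
        return self.n_bands_kept if self.feature_type == "mel" else self.win_length // 2 + 1

    def fingerprint(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


STFT_CONFIG = FeatureConfig(feature_type="stft", analysis_sr=1000)


@dataclass
class SpectrogramFeature:
    values: np.ndarray = field(repr=False)
    config: FeatureConfig = STFT_CONFIG
    window: LabeledWindow | None = None


def segment_and_label(recording: AudioRecording,
                      events: list[ApneaEvent]) -> list[LabeledWindow]:
    """Cut into 6-s windows; apnea iff one event spans the whole window."""
    if recording.duration_s < WINDOW_S:
        raise ValueError(
            f"recording {recording.patient_id} is {recording.duration_s:.1f} s, "
            f"shorter than one {WINDOW_S:.0f}-s window"
        )
    n_windows = int(recording.duration_s // WINDOW_S)
    windows = []
    for k in range(n_windows):
        start, end = k * WINDOW_S, (k + 1) * WINDOW_S
        covered = any(ev.onset_s <= start and ev.offset_s >= end for ev in events)
        windows.append(LabeledWindow(
            patient_id=recording.patient_id, start_s=start, end_s=end,
            label="apnea" if covered else "non_apnea",
        ))
    return windows


def downsample(recording: AudioRecording, target_sr: int) -> AudioRecording:
    """Anti-aliased polyphase resampling to a lower rate."""
    if target_sr > recording.sample_rate:
        raise ValueError(
            f"upsampling {recording.sample_rate} -> {target_sr} Hz not supported"
        )
    if target_sr == recording.sample_rate:
        return recording
    frac = Fraction(target_sr, recording.sample_rate)
    out = sps.resample_poly(recording.samples, frac.numerator, frac.denominator)
    return AudioRecording(patient_id=recording.patient_id, sample_rate=target_sr,
                          samples=out)


def _frame_signal(x: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Centred analysis frames of win_length samples every hop_length samples."""
    win, hop = cfg.win_length, cfg.hop_length
    if cfg.center_padding:
        x = np.pad(x, win // 2, mode="reflect")
    n_frames = 1 + (len(x) - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _stft_matrix(x: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Complex STFT, (bins, frames), Hann-windowed."""
    frames = _frame_signal(x, cfg)
    window = sps.get_window("hann", cfg.win_length, fftbins=True)
    return np.fft.rfft(frames * window, axis=1).T


def mel_filterbank(sr: int, n_fft: int, n_mels: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Slaney-style triangular Mel filterbank, (n_mels, n_fft//2 + 1)."""
    fmax = fmax or sr / 2.0

    def hz_to_mel(f):
        f = np.asarray(f, dtype=np.float64)
        mel = f / (200.0 / 3.0)
        log_region = f >= 1000.0
        mel = np.where(log_region, 15.0 + np.log(np.maximum(f, 1e-12) / 1000.0) / np.log(6.4) * 27.0, mel)
        return mel

    def mel_to_hz(m):
        m = np.asarray(m, dtype=np.float64)
        f = m * (200.0 / 3.0)
        log_region = m >= 15.0
        return np.where(log_region, 1000.0 * np.exp(np.log(6.4) * (m - 15.0) / 27.0), f)

    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    weights = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - mid, 1e-12)
        weights[i] = np.maximum(0.0, np.minimum(up, down))
        weights[i] *= 2.0 / (hi - lo)  # Slaney area normalisation
    return weights


def _postprocess(spec: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    if cfg.log_scale:
        spec = 10.0 * np.log10(np.maximum(spec, LOG_FLOOR))
    if cfg.standardize:
        std = spec.std()
        spec = (spec - spec.mean()) / std if std > 0 else np.zeros_like(spec)
    return spec


def mel_spectrogram(samples: np.ndarray, config: FeatureConfig,
                    window: LabeledWindow | None = None) -> SpectrogramFeature:
    """32-band Mel power spectrogram at 16 kHz, truncated to the lowest bands kept."""
    if config.feature_type != "mel":
        raise ValueError("config.feature_type must be 'mel'")
    expected = int(WINDOW_S * config.analysis_sr)
    if len(samples) != expected:
        raise ValueError(f"expected {expected} samples at {config.analysis_sr} Hz, "
                         f"got {len(samples)}")
    power = np.abs(_stft_matrix(np.asarray(samples, dtype=np.float64), config)) ** 2
    fb = mel_filterbank(config.analysis_sr, config.win_length, config.n_mels_total)
    mel = fb @ power
    mel = mel[: config.n_bands_kept]  # band truncation, lowest frequencies first
    return SpectrogramFeature(values=_postprocess(mel, config), config=config,
                              window=window)


def stft_spectrogram(samples: np.ndarray, config: FeatureConfig = STFT_CONFIG,
                     window: LabeledWindow | None = None) -> SpectrogramFeature:
    """Linear-frequency magnitude STFT of the 1 kHz signal (1025 bins x 24 frames)."""
    if config.feature_type != "stft":
        raise ValueError("config.feature_type must be 'stft'")
    expected = int(WINDOW_S * config.analysis_sr)
    if len(samples) != expected:
        raise ValueError(f"expected {expected} samples at {config.analysis_sr} Hz, "
                         f"got {len(samples)}")
    mag = np.abs(_stft_matrix(np.asarray(samples, dtype=np.float64), config))
    return SpectrogramFeature(values=_postprocess(mag, config), config=config,
                              window=window)


def extract_features(recording: AudioRecording, events: list[ApneaEvent],
                     config: FeatureConfig) -> list[SpectrogramFeature]:
    """Segment, label, and featurize a whole recording at its analysis rate."""
    windows = segment_and_label(recording, events)
    track = downsample(recording, config.analysis_sr) \
        if config.analysis_sr != recording.sample_rate else recording
    sr = config.analysis_sr
    wlen = int(WINDOW_S * sr)
    feats = []
    for w in windows:
        chunk = track.samples[int(w.start_s * sr): int(w.start_s * sr) + wlen]
        if config.feature_type == "mel":
            feats.append(mel_spectrogram(chunk, config, window=w))
        else:
            feats.append(stft_spectrogram(chunk, config, window=w))
    return feats


def save_features(feats: list[SpectrogramFeature], out_dir: str | os.PathLike) -> None:
    """Persist one array file per window plus a JSON sidecar manifest."""
    os.makedirs(out_dir, exist_ok=True)
    records = []
    for i, f in enumerate(feats):
        name = f"win_{i:05d}.npy"
        np.save(os.path.join(out_dir, name), f.values)
        w = f.window
        records.append({
            "file": name,
            "patient_id": w.patient_id if w else None,
            "start_s": w.start_s if w else None,
            "end_s": w.end_s if w else None,
            "label": w.label if w else None,
            "config": asdict(f.config),
        })
    with open(os.path.join(out_dir, "features.json"), "w") as fh:
        json.dump(records, fh, indent=1)


def load_features(in_dir: str | os.PathLike) -> list[SpectrogramFeature]:
    with open(os.path.join(in_dir, "features.json")) as fh:
        records = json.load(fh)
    feats = []
    for rec in records:
        values = np.load(os.path.join(in_dir, rec["file"]))
        cfg = FeatureConfig(**rec["config"])
        window = None
        if rec["patient_id"] is not None:
            window = LabeledWindow(patient_id=rec["patient_id"], start_s=rec["start_s"],
                                   end_s=rec["end_s"], label=rec["label"])
        feats.append(SpectrogramFeature(values=values, config=cfg, window=window))
    return feats
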