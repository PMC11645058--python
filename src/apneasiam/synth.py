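"""Synthetic annotated tracheal-audio cohorts.

The generator emulates the statistical structure of overnight tracheal
recordings: breathing appears as periodic band-limited noise bursts (one
Hann-shaped burst per breath period), apnea events of at least 10 s
suppress those bursts, and broadband ambient noise is mixed in at a
configurable signal-to-noise ratio.  "Corrupted" patients — emulating a
malfunctioning device or an external noise source — get an SNR at or
below 0 dB, drowning the breathing structure entirely.

Roughly 30% of each track lies inside apnea events by default, matching
the class balance the detection pipeline is designed for.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .dataio import (
    ApneaEvent,
    AudioRecording,
    EVENT_GRID_S,
    store_events,
    store_recording,
    validate_events,
)

SYNTH_SAMPLE_RATE = 16000
# Ambient noise is broadband (0 to Nyquist) while breathing occupies only
# ~700 Hz of the 8 kHz band, so a broadband SNR of 0 dB still leaves about
# +10 dB of in-band SNR and clearly visible breathing structure.  The
# corrupted-patient default is chosen so that the in-band noise power exceeds
# the breathing power by an order of magnitude (in-band SNR ~ -15 dB): the
# bursts then perturb the in-band level by under 3%, i.e. the structure is
# genuinely drowned.
CORRUPTED_SNR_DB = -25.0


@dataclass(frozen=True)
class SyntheticPatientConfig:
    """Parameters of one synthetic overnight recording.

    ambient_snr_db is the ratio of breathing-burst power to ambient noise
    power; corrupted patients use values <= 0 dB.
    """

    duration_s: float = 600.0
    breath_period_s: float = 4.0
    burst_duration_s: float = 1.2
    burst_band_hz: tuple[float, float] = (100.0, 800.0)
    apnea_fraction_target: float = 0.30
    apnea_duration_range_s: tuple[float, float] = (10.0, 40.0)
    apnea_suppression_db: float = -40.0
    ambient_snr_db: float = 15.0
    corrupted: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.duration_s < 60:
            raise ValueError("duration_s must be at least 60 s")
        if self.breath_period_s <= self.burst_duration_s:
            raise ValueError("breath_period_s must exceed burst_duration_s")
        lo, hi = self.apnea_duration_range_s
        if lo < 10.0:
            raise ValueError("apnea events must last at least 10 s")
        if hi < lo:
            raise ValueError("apnea_duration_range_s must be (min, max) with min <= max")
        if not 0.0 <= self.apnea_fraction_target < 1.0:
            raise ValueError("apnea_fraction_target must lie in [0, 1)")


def _draw_event_durations(rng: np.random.Generator, cfg: SyntheticPatientConfig) -> list[float]:
    """Durations on the 0.5-s grid whose sum lands within +-5 pp of the target."""
    target = cfg.apnea_fraction_target * cfg.duration_s
    if target <= 0:
        return []
    lo, hi = cfg.apnea_duration_range_s
    tol = 0.05 * cfg.duration_s
    durations: list[float] = []
    total = 0.0
    while total < target - tol:
        d = rng.uniform(lo, hi)
        d = round(d / EVENT_GRID_S) * EVENT_GRID_S
        d = min(max(d, lo), hi)
        if total + d > target + tol:
            # trim the last event back toward the target, keeping it valid
            d = round((target - total) / EVENT_GRID_S) * EVENT_GRID_S
            if d < lo:
                d = lo
        durations.append(d)
        total += d
    return durations


def _place_events(rng: np.random.Generator, cfg: SyntheticPatientConfig,
                  durations: list[float]) -> list[ApneaEvent]:
    """Rejection-sample non-overlapping start times with >= one breath period gap."""
    if not durations:
        return []
    gap = cfg.breath_period_s
    needed = sum(durations) + gap * (len(durations) + 1)
    if needed > cfg.duration_s:
        raise ValueError(
            f"apnea target infeasible: {sum(durations):.0f} s of events plus spacing "
            f"exceed the {cfg.duration_s:.0f} s recording"
        )
    n_grid = int(round(cfg.duration_s / EVENT_GRID_S))
    for _ in range(1000):
        starts = []
        ok = True
        for d in durations:
            max_start = cfg.duration_s - gap - d
            placed = False
            for _ in range(200):
                s = rng.integers(int(gap / EVENT_GRID_S), int(max_start / EVENT_GRID_S) + 1)
                s = s * EVENT_GRID_S
                if all(s + d + gap <= s2 or s >= s2 + d2 + gap
                       for s2, d2 in zip(starts, durations)):
                    starts.append(s)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            events = [ApneaEvent(onset_s=s, offset_s=round((s + d) / EVENT_GRID_S) * EVENT_GRID_S)
                      for s, d in zip(starts, durations)]
            return validate_events(events, warn_short=False)
    raise ValueError("could not place apnea events without overlap; lower the target")


def _breathing_track(rng: np.random.Generator, cfg: SyntheticPatientConfig,
                     n: int, sr: int) -> np.ndarray:
    """Band-limited noise gated by one Hann burst per breath period."""
    noise = rng.standard_normal(n)
    sos = signal.butter(4, cfg.burst_band_hz, btype="bandpass", fs=sr, output="sos")
    carrier = signal.sosfilt(sos, noise)
    envelope = np.zeros(n)
    burst_len = int(round(cfg.burst_duration_s * sr))
    burst = np.hanning(burst_len)
    period = cfg.breath_period_s
    t = 0.0
    while t < cfg.duration_s:
        start = int(round(t * sr))
        stop = min(start + burst_len, n)
        envelope[start:stop] = burst[: stop - start]
        t += period
    return carrier * envelope


def generate_patient(config: SyntheticPatientConfig,
                     patient_id: str = "p000") -> tuple[AudioRecording, list[ApneaEvent]]:
    """Synthesize one annotated recording at 16 kHz, deterministically from the seed."""
    sr = SYNTH_SAMPLE_RATE
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * sr))
    durations = _draw_event_durations(rng, config)
    events = _place_events(rng, config, durations)

    breathing = _breathing_track(rng, config, n, sr)
    suppression = 10.0 ** (config.apnea_suppression_db / 20.0)
    gain = np.ones(n)
    for ev in events:
        gain[int(ev.onset_s * sr): int(ev.offset_s * sr)] = suppression
    clean = breathing * gain

    breath_power = np.mean(breathing ** 2)
    snr = CORRUPTED_SNR_DB if config.corrupted and config.ambient_snr_db > 0 \
        else config.ambient_snr_db
    noise_power = breath_power / (10.0 ** (snr / 10.0))
    ambient = rng.standard_normal(n) * np.sqrt(noise_power)
    mix = clean + ambient

    peak = np.max(np.abs(mix))
    if peak > 0:
        mix = mix * (0.9 / peak)
    recording = AudioRecording(patient_id=patient_id, sample_rate=sr, samples=mix)
    return recording, events


def generate_cohort(n_patients: int, base_config: SyntheticPatientConfig,
                    corrupted_ids: set[str] | None = None,
                    out_dir: str | os.PathLike | None = None) -> pd.DataFrame:
    """Generate a cohort; returns the manifest (patient_id, paths, corrupted flag).

    Per-patient seeds are spawned deterministically from the base seed, so
    one patient's audio never depends on another's. When ``out_dir`` is
    given, a WAV plus annotation CSV per patient and a ``manifest.csv`` are
    written there; otherwise recordings stay in memory in the returned
    manifest's ``recording``/``events`` columns.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    corrupted_ids = corrupted_ids or set()
    ids = [f"p{i:03d}" for i in range(n_patients)]
    unknown = corrupted_ids - set(ids)
    if unknown:
        raise ValueError(f"corrupted_ids not in cohort: {sorted(unknown)}")
    children = np.random.SeedSequence(base_config.seed).spawn(n_patients)
    rows = []
    for pid, child in zip(ids, children):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = replace(base_config, seed=seed, corrupted=pid in corrupted_ids)
        rec, events = generate_patient(cfg, patient_id=pid)
        row = {"patient_id": pid, "corrupted": pid in corrupted_ids}
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            wav_path = os.path.join(out_dir, f"{pid}.wav")
            ev_path = os.path.join(out_dir, f"{pid}_events.csv")
            store_recording(rec, wav_path)
            store_events(events, ev_path)
            row.update(wav_path=wav_path, events_path=ev_path)
        else:
            row.update(recording=rec, events=events)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def event_fraction(events: list[ApneaEvent], duration_s: float) -> float:
    """Fraction of the recording covered by apnea events."""
    return sum(e.duration_s for e in events) / duration_s
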