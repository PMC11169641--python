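"""Passage-reading (prosody) analysis: pauses, net speech rate, running pitch.

Pauses are stretches that are both unvoiced and below a broadband-energy
floor (fricatives and plosives carry energy, true pauses do not), with a
configurable minimum duration; the net syllable rate divides the known
syllable count of the passage by the reading time excluding pauses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_core import (
    AudioRecording,
    amplitude_envelope,
    intensity_contour,
    track_f0,
    trim_silence,
)
from .errors import ArgumentError, InconsistentInputError

#: Sentinel for "no pauses detected" in the DPI feature.
NO_PAUSES = float("nan")


@dataclass(frozen=True)
class PauseSet:
    """Detected pauses as ordered, disjoint half-open (start_s, end_s) intervals."""

    pauses: tuple[tuple[float, float], ...]
    min_pause_ms: float

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for s, e in self.pauses:
            if e <= s:
                raise ArgumentError("pause intervals must have positive length")
            if s < prev_end:
                raise ArgumentError("pause intervals must be ordered and disjoint")
            prev_end = e

    @property
    def durations_ms(self) -> np.ndarray:
        return np.array([(e - s) * 1000.0 for s, e in self.pauses])

    @property
    def total_s(self) -> float:
        return float(sum(e - s for s, e in self.pauses))

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.asarray(self.pauses).reshape(-1, 2),
            delimiter=",",
            header="start_s,end_s",
            comments="",
            fmt="%.4f",
        )


@dataclass(frozen=True)
class ProsodyFeatures:
    TotalDur: float  # s, trimmed reading time
    NSR: float  # syllables / s of net speech time
    DPI: float  # ms, median pause duration (NaN when no pauses)
    rF0: float  # Hz
    rSTD: float  # Hz
    rvF0: float  # %
    rvAm: float  # %


def detect_pauses(
    rec: AudioRecording,
    min_pause_ms: float = 30.0,
    floor_db: float = -25.0,
) -> PauseSet:
    """Find pauses: intervals both low-energy and unvoiced, >= ``min_pause_ms``.

    Candidate intervals come from the amplitude envelope falling below
    ``floor_db`` relative to the recording's speech level (90th percentile of
    the envelope); candidates containing confidently voiced frames are
    rejected; survivors shorter than the minimum duration are discarded.
    """
    if min_pause_ms <= 0:
        raise ArgumentError("min_pause_ms must be positive")
    env = amplitude_envelope(rec, smooth_ms=10.0, hop_s=0.002)
    speech_level = np.percentile(env.values, 90)
    if speech_level <= 0:
        return PauseSet(pauses=(), min_pause_ms=min_pause_ms)
    low = env.values < speech_level * 10 ** (floor_db / 20.0)
    f0 = track_f0(rec)

    intervals: list[tuple[float, float]] = []
    in_run = False
    start = 0.0
    for i, flag in enumerate(low):
        if flag and not in_run:
            start = env.times[i]
            in_run = True
        elif not flag and in_run:
            intervals.append((start, env.times[i]))
            in_run = False
    if in_run:
        intervals.append((start, env.times[-1] + env.hop))

    kept = []
    margin = f0.frame_length / 2.0
    for s, e in intervals:
        if (e - s) * 1000.0 < min_pause_ms:
            continue
        inside = (f0.times > s + margin) & (f0.times < e - margin)
        if np.any(f0.voiced[inside]):
            continue
        kept.append((float(s), float(e)))
    return PauseSet(pauses=tuple(kept), min_pause_ms=min_pause_ms)


def prosody_features(
    rec: AudioRecording,
    pauses: PauseSet,
    n_syllables: int = 105,
) -> ProsodyFeatures:
    """Passage features from a (trimmed) recording and its detected pauses.

    ``n_syllables`` is the syllable count of the read passage (105 for the
    standard weather-report text); NSR divides it by the net reading time.
    Running F0 statistics use all voiced frames; amplitude variation uses
    linear frame amplitudes over speech (non-pause) frames.
    """
    if n_syllables < 1:
        raise ArgumentError("n_syllables must be >= 1")
    total_dur = rec.duration
    net = total_dur - pauses.total_s
    if net <= 0:
        raise InconsistentInputError(
            f"pauses ({pauses.total_s:.2f} s) exceed the recording ({total_dur:.2f} s)"
        )
    nsr = n_syllables / net
    dpi = float(np.median(pauses.durations_ms)) if pauses.pauses else NO_PAUSES

    f0 = track_f0(rec)
    f0_vals = f0.voiced_values
    if f0_vals.size < 2:
        rf0 = rstd = rvf0 = float("nan")
    else:
        rf0 = float(np.mean(f0_vals))
        rstd = float(np.std(f0_vals, ddof=1))
        rvf0 = 100.0 * rstd / rf0

    intensity = intensity_contour(rec)
    speech_mask = np.ones(len(intensity), dtype=bool)
    for s, e in pauses.pauses:
        speech_mask &= ~((intensity.times >= s) & (intensity.times < e))
    lin = 10.0 ** (intensity.values[speech_mask] / 20.0)
    rvam = 100.0 * float(np.std(lin, ddof=1) / np.mean(lin)) if lin.size > 1 else float("nan")
    return ProsodyFeatures(
        TotalDur=float(total_dur),
        NSR=float(nsr),
        DPI=dpi,
        rF0=rf0,
        rSTD=rstd,
        rvF0=rvf0,
        rvAm=rvam,
    )


def analyze_passage(
    rec: AudioRecording,
    n_syllables: int = 105,
    min_pause_ms: float = 30.0,
) -> tuple[ProsodyFeatures, PauseSet]:
    """End-to-end passage analysis: trim, detect pauses, compute features."""
    trimmed, _ = trim_silence(rec)
    pauses = detect_pauses(trimmed, min_pause_ms=min_pause_ms)
    return prosody_features(trimmed, pauses, n_syllables=n_syllables), pauses
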