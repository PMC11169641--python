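"""Sustained-vowel (phonation) analysis and the vowel space area.

Phonatory instability in Parkinson's disease shows up as elevated F0
variability and amplitude variability during a sustained /a/; articulatory
undershoot shrinks the F1-F2 triangle spanned by /a/, /i/ and /u/.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_core import (
    AudioRecording,
    hnr,
    intensity_contour,
    lpc_formants,
    track_f0,
    voicing_segments,
)
from .errors import ArgumentError, InsufficientPhonationError, NotComputableError


@dataclass(frozen=True)
class PhonationFeatures:
    F0: float  # Hz, mean over voiced frames
    F0std: float  # Hz
    vF0: float  # %, 100*F0std/F0
    Ampstd: float  # dB, SD of frame levels over voiced frames
    vAmp: float  # %, 100*SD/mean of linear frame RMS amplitudes
    MPT: float  # s, longest voiced segment
    HNR: float  # dB
    F1: float  # Hz, median formant of this vowel
    F2: float  # Hz


def phonation_features(
    rec: AudioRecording,
    f0_min: float = 75.0,
    f0_max: float = 400.0,
    min_voiced_s: float = 0.5,
) -> PhonationFeatures:
    """Sustained-vowel statistics over voiced frames only.

    F0 statistics come from the autocorrelation F0 contour; amplitude
    statistics from the RMS intensity contour restricted to voiced frames
    (the percentage variation uses linear amplitudes, because a percentage
    of dB values is ill-defined); MPT is the longest voiced segment, so
    leading/trailing silence cannot inflate it.
    """
    f0_track = track_f0(rec, f0_min=f0_min, f0_max=f0_max)
    segments = voicing_segments(f0_track)
    voiced_total = sum(e - s for s, e in segments)
    if voiced_total < min_voiced_s:
        raise InsufficientPhonationError(
            f"only {voiced_total:.2f} s voiced; need >= {min_voiced_s} s"
        )
    f0_vals = f0_track.voiced_values
    f0_mean = float(np.mean(f0_vals))
    f0_sd = float(np.std(f0_vals, ddof=1))

    intensity = intensity_contour(rec)
    n = min(len(intensity), len(f0_track))
    voiced_mask = f0_track.voiced[:n]
    db_vals = intensity.values[:n][voiced_mask]
    lin_vals = 10.0 ** (db_vals / 20.0)
    amp_sd_db = float(np.std(db_vals, ddof=1))
    v_amp = 100.0 * float(np.std(lin_vals, ddof=1) / np.mean(lin_vals))

    mpt = max(e - s for s, e in segments)
    try:
        hnr_db = hnr(rec, f0_min=f0_min, f0_max=f0_max)
    except NotComputableError:
        hnr_db = np.nan

    f1_track, f2_track = lpc_formants(rec, n_formants=3)[:2]
    f1_med = _median_in_segments(f1_track, segments)
    f2_med = _median_in_segments(f2_track, segments)
    return PhonationFeatures(
        F0=f0_mean,
        F0std=f0_sd,
        vF0=100.0 * f0_sd / f0_mean,
        Ampstd=amp_sd_db,
        vAmp=v_amp,
        MPT=float(mpt),
        HNR=hnr_db,
        F1=f1_med,
        F2=f2_med,
    )


def _median_in_segments(track, segments) -> float:
    """Median of defined track values whose frame centers fall in voiced segments."""
    mask = np.zeros(len(track), dtype=bool)
    for s, e in segments:
        mask |= (track.times >= s) & (track.times < e)
    vals = track.values[mask & track.voiced]
    return float(np.median(vals)) if vals.size else float("nan")


def vowel_space_area(
    f1_a: float, f2_a: float, f1_i: float, f2_i: float, f1_u: float, f2_u: float
) -> float:
    """Area (Hz^2) of the F1-F2 triangle spanned by /a/, /i/, /u/ (shoelace formula)."""
    vals = (f1_a, f2_a, f1_i, f2_i, f1_u, f2_u)
    if any(not np.isfinite(v) or v <= 0 for v in vals):
        raise ArgumentError(f"all six formants must be positive and finite, got {vals}")
    return 0.5 * abs(
        f1_a * (f2_i - f2_u) + f1_i * (f2_u - f2_a) + f1_u * (f2_a - f2_i)
    )
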