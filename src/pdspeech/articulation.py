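"""/i/-/u/ alternation analysis: F2 transition cycles and their statistics.

During fast /i/-/u/ repetition the second formant swings between a high
(/i/) and a low (/u/) target; reduced magnitude, rate or regularity of
those swings indexes impaired tongue-movement control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, medfilt

from .audio_core import AudioRecording, FrameTrack, lpc_formants, track_f0
from .errors import ArgumentError, InsufficientCyclesError


@dataclass(frozen=True)
class F2Cycle:
    """One alternation cycle: an F2 peak (/i/) and the following trough (/u/)."""

    peak_time_s: float
    trough_time_s: float
    f2_peak: float
    f2_trough: float
    cycle_period_s: float | None = None  # to the next peak; None for the last

    def __post_init__(self) -> None:
        if self.f2_peak <= self.f2_trough:
            raise ArgumentError("cycle requires f2_peak > f2_trough")
        if self.peak_time_s >= self.trough_time_s:
            raise ArgumentError("peak must precede its trough")
        if self.cycle_period_s is not None and self.cycle_period_s <= 0:
            raise ArgumentError("cycle_period_s must be positive")


@dataclass(frozen=True)
class ArticulationFeatures:
    F2magn: float  # Hz, mean peak-trough excursion
    F2rate: float  # cycles / s of voiced task time
    F2reg: float  # %, CV of cycle periods (lower = more regular)
    F2aver: float  # Hz, mean of the voiced F2 track
    F2min: float  # Hz
    F2max: float  # Hz


def _smooth_track(f2: FrameTrack, smooth_ms: float, outlier_hz: float = 400.0) -> np.ndarray:
    """Interpolate gaps, reject LPC glitches against a median curve, and smooth."""
    vals = f2.values.copy()
    defined = np.isfinite(vals)
    if defined.sum() < 3:
        raise InsufficientCyclesError("F2 track has too few defined frames")
    vals = np.interp(f2.times, f2.times[defined], vals[defined])
    kernel = int(round(smooth_ms / 1000.0 / f2.hop))
    kernel = max(3, kernel + (kernel + 1) % 2)  # odd, >= 3
    med = medfilt(vals, kernel)
    cleaned = np.where(np.abs(vals - med) > outlier_hz, med, vals)
    return np.convolve(cleaned, np.ones(3) / 3.0, mode="same")


def detect_f2_cycles(
    f2: FrameTrack,
    min_prominence_hz: float = 200.0,
    smooth_ms: float = 50.0,
) -> list[F2Cycle]:
    """Detect /i/-/u/ alternation cycles on the smoothed F2 track.

    The centered track is segmented by a hysteresis state machine: a cycle
    boundary is the midline crossing on each low-to-high transition, which
    falls on the fast formant sweep and therefore localizes cycle timing far
    better than the broad vowel plateaus.  Within each cycle the peak (/i/)
    and trough (/u/) are the track extremes.  The alternation must exceed
    ``min_prominence_hz`` on both sides of the midline; fewer than two
    complete cycles raises :class:`InsufficientCyclesError`.
    """
    smooth = _smooth_track(f2, smooth_ms)
    times = f2.times
    mid = float(np.median(smooth))
    lo_q, hi_q = np.percentile(smooth, [5, 95])
    if hi_q - lo_q < 2 * min_prominence_hz:
        raise InsufficientCyclesError(
            f"F2 excursion {hi_q - lo_q:.0f} Hz is below the "
            f"{2 * min_prominence_hz:.0f} Hz alternation minimum"
        )
    s = smooth - mid
    hyst = max(min_prominence_hz / 2.0, 0.25 * (hi_q - lo_q) / 2.0)

    half_fit = max(2, int(round(0.030 / f2.hop)))  # +/- 30 ms regression window

    def _refined_crossing(i: int) -> float:
        """Up-crossing time from a local linear fit over the transition slope."""
        j0, j1 = max(0, i - half_fit), min(s.size, i + half_fit + 1)
        tt, yy = times[j0:j1], s[j0:j1]
        slope, intercept = np.polyfit(tt, yy, 1)
        if slope > 0:
            t_cross = -intercept / slope
            if times[j0] - f2.hop <= t_cross <= times[j1 - 1] + f2.hop:
                return float(t_cross)
        frac = -s[i - 1] / (s[i] - s[i - 1])
        return float(times[i - 1] + frac * f2.hop)

    state = 0  # 1 after confirming high, -1 after confirming low
    last_up_cross: float | None = None
    boundaries: list[float] = []
    for i in range(1, s.size):
        if s[i - 1] < 0 <= s[i]:
            last_up_cross = _refined_crossing(i)
        if s[i] > hyst and state != 1:
            if state == -1 and last_up_cross is not None:
                boundaries.append(last_up_cross)
            elif state == 0:
                boundaries.append(last_up_cross if last_up_cross is not None else float(times[i]))
            state = 1
        elif s[i] < -hyst and state != -1:
            state = -1
    if len(boundaries) < 2:
        raise InsufficientCyclesError(f"only {len(boundaries)} alternation cycles detected")

    cycles: list[F2Cycle] = []
    for j, start in enumerate(boundaries):
        end = boundaries[j + 1] if j + 1 < len(boundaries) else float(times[-1]) + f2.hop
        seg = (times >= start) & (times < end)
        if not np.any(seg):
            continue
        seg_vals = smooth[seg]
        seg_times = times[seg]
        i_pk = int(np.argmax(seg_vals))
        # trough searched after the peak so the pair is time-ordered
        after = seg_vals[i_pk:]
        if after.size < 2:
            continue
        i_tr = i_pk + int(np.argmin(after))
        if seg_vals[i_pk] <= seg_vals[i_tr] or i_tr == i_pk:
            continue
        period = boundaries[j + 1] - start if j + 1 < len(boundaries) else None
        cycles.append(
            F2Cycle(
                peak_time_s=float(seg_times[i_pk]),
                trough_time_s=float(seg_times[i_tr]),
                f2_peak=float(seg_vals[i_pk]),
                f2_trough=float(seg_vals[i_tr]),
                cycle_period_s=period,
            )
        )
    if len(cycles) < 2:
        raise InsufficientCyclesError(f"only {len(cycles)} complete cycles detected")
    return cycles


def articulation_features(
    cycles: list[F2Cycle], f2: FrameTrack, voiced_duration_s: float | None = None
) -> ArticulationFeatures:
    """The six F2-alternation features from detected cycles and the raw track.

    F2rate divides the cycle count by the voiced task duration (defaulting to
    the track's defined-frame span); F2reg is the coefficient of variation of
    cycle periods in percent, so lower values mean more regular alternation.
    """
    if len(cycles) < 2:
        raise InsufficientCyclesError("need >= 2 cycles")
    if voiced_duration_s is None:
        voiced_duration_s = float(np.sum(f2.voiced) * f2.hop)
    if voiced_duration_s <= 0:
        raise ArgumentError("voiced_duration_s must be positive")
    excursions = np.array([c.f2_peak - c.f2_trough for c in cycles])
    periods = np.array([c.cycle_period_s for c in cycles if c.cycle_period_s is not None])
    track_vals = f2.voiced_values
    track_vals = track_vals[np.isfinite(track_vals)]
    return ArticulationFeatures(
        F2magn=float(np.mean(excursions)),
        F2rate=len(cycles) / voiced_duration_s,
        F2reg=100.0 * float(np.std(periods, ddof=1) / np.mean(periods)),
        F2aver=float(np.mean(track_vals)),
        F2min=float(np.min(track_vals)),
        F2max=float(np.max(track_vals)),
    )


def extract_f2_track(
    rec: AudioRecording,
    f2_band: tuple[float, float] = (500.0, 3200.0),
    frame_s: float = 0.02,
    max_bandwidth: float = 600.0,
) -> FrameTrack:
    """Second-formant track for alternation analysis.

    Rapidly sweeping formants appear broadened to LPC, so a looser bandwidth
    cap and shorter frames are used than for sustained vowels; per frame the
    lowest resonance inside ``f2_band`` is taken as F2 (F1 sits below the
    band during /i/-/u/).
    """
    tracks = lpc_formants(rec, n_formants=3, frame_s=frame_s, max_bandwidth=max_bandwidth)
    vals = np.stack([t.values for t in tracks])
    lo, hi = f2_band
    in_band = np.where((vals > lo) & (vals < hi), vals, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        f2_vals = np.nanmin(in_band, axis=0)
    base = tracks[0]
    return FrameTrack(
        times=base.times,
        values=f2_vals,
        voiced=np.isfinite(f2_vals),
        frame_length=base.frame_length,
        hop=base.hop,
    )


def analyze_iu(rec: AudioRecording) -> tuple[ArticulationFeatures, list[F2Cycle]]:
    """End-to-end /i/-/u/ analysis: formant tracking, cycle detection, features."""
    f2 = extract_f2_track(rec)
    f0 = track_f0(rec)
    voiced_s = float(np.sum(f0.voiced) * f0.hop)
    cycles = detect_f2_cycles(f2)
    return articulation_features(cycles, f2, voiced_duration_s=voiced_s or None), cycles
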