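"""Diadochokinesis (/pa/ repetition) analysis.

Detects syllable events on the amplitude envelope (peak picking with a
prominence threshold, onsets/offsets at half-prominence crossings) and
derives the eight DDK features: rate, mean/SD/CV of syllable period,
period perturbation (jitter), SD/CV of peak intensity, and voice onset
time.  Slowed and unstable /pa/ trains are a hallmark of hypokinetic
dysarthria, so these features index articulatory speed and stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .audio_core import AudioRecording, FrameTrack, amplitude_envelope, track_f0
from .errors import ArgumentError, InsufficientEventsError, NotComputableError

#: Offset making envelope dB values positive on a speech-level-like scale
#: (dB re 1% of full scale: a -6 dBFS peak maps to ~34 dB), so intensity
#: coefficients of variation are well defined.
DB_REF_OFFSET = 40.0


def _to_db(x: np.ndarray | float) -> np.ndarray | float:
    return 20.0 * np.log10(np.maximum(x, 1e-10)) + DB_REF_OFFSET


@dataclass(frozen=True)
class SyllableEvent:
    """One detected syllable: half-prominence onset/offset around an envelope peak."""

    onset_s: float
    peak_s: float
    offset_s: float
    peak_intensity_db: float
    period_s: float | None = None  # to the next event's peak; None for the last

    def __post_init__(self) -> None:
        if not (self.onset_s < self.peak_s < self.offset_s):
            raise ArgumentError("event must satisfy onset < peak < offset")
        if self.period_s is not None and self.period_s <= 0:
            raise ArgumentError("period_s must be positive")


@dataclass(frozen=True)
class DdkFeatures:
    DDKavr: float  # syllables / s
    DDKavp: float  # ms
    DDKsdp: float  # ms
    DDKcvp: float  # %
    DDKjit: float  # %
    DDKsdi: float  # dB
    DDKcvi: float  # %
    VOT: float | None = None  # ms; filled by measure_vot


def detect_syllables(
    envelope: FrameTrack,
    min_prominence: float = 0.1,
    min_period_ms: float = 100.0,
) -> list[SyllableEvent]:
    """Pick syllable peaks on the envelope and delimit them at half prominence.

    ``min_prominence`` is a fraction of the envelope maximum; peaks closer
    together than ``min_period_ms`` are suppressed.  An empty result (with a
    warning) is returned when nothing is found — a silent recording is a data
    problem, not a programming error.
    """
    if not 0.0 < min_prominence < 1.0:
        raise ArgumentError("min_prominence must lie in (0, 1)")
    if min_period_ms <= 0:
        raise ArgumentError("min_period_ms must be positive")
    env = envelope.values
    peak_env = env.max() if env.size else 0.0
    if peak_env <= 0:
        warnings.warn("silent envelope: no syllables detected")
        return []
    distance = max(1, int(round(min_period_ms / 1000.0 / envelope.hop)))
    peaks, props = find_peaks(env, prominence=min_prominence * peak_env, distance=distance)
    if peaks.size == 0:
        warnings.warn("no envelope peaks above the prominence threshold")
        return []

    events: list[SyllableEvent] = []
    times = envelope.times
    prominences = props["prominences"]
    for j, p in enumerate(peaks):
        level = env[p] - 0.5 * prominences[j]
        i = p
        while i > 0 and env[i] > level:
            i -= 1
        onset = times[i]
        i = p
        while i < env.size - 1 and env[i] > level:
            i += 1
        offset = times[i]
        if not onset < times[p] < offset:  # degenerate plateau; widen by one hop
            onset = times[p] - envelope.hop / 2
            offset = times[p] + envelope.hop / 2
        events.append(
            SyllableEvent(
                onset_s=float(onset),
                peak_s=float(times[p]),
                offset_s=float(offset),
                peak_intensity_db=float(_to_db(env[p])),
            )
        )
    # attach peak-to-peak periods
    with_periods = []
    for j, ev in enumerate(events):
        period = events[j + 1].peak_s - ev.peak_s if j + 1 < len(events) else None
        with_periods.append(
            SyllableEvent(ev.onset_s, ev.peak_s, ev.offset_s, ev.peak_intensity_db, period)
        )
    return with_periods


def ddk_features(events: list[SyllableEvent], task_duration_s: float) -> DdkFeatures:
    """The seven envelope-derived DDK features (VOT is measured separately).

    DDKavr is the syllable count over the analyzed task duration; period
    statistics use peak-to-peak intervals; DDKjit is the mean absolute
    consecutive-period difference relative to the mean period (a local
    jitter analog); intensity statistics use envelope peak levels in dB.
    """
    if task_duration_s <= 0:
        raise ArgumentError("task_duration_s must be positive")
    if len(events) < 3:
        raise InsufficientEventsError(
            "need >= 3 syllable events for DDKsdp/DDKcvp/DDKjit/DDKsdi/DDKcvi; "
            f"got {len(events)}"
        )
    periods_ms = np.array([ev.period_s for ev in events if ev.period_s is not None]) * 1000.0
    durations_ms = np.array([(ev.offset_s - ev.onset_s) * 1000.0 for ev in events])
    intensities = np.array([ev.peak_intensity_db for ev in events])

    ddkavr = len(events) / task_duration_s
    ddkavp = float(np.mean(durations_ms))
    ddksdp = float(np.std(periods_ms, ddof=1))
    ddkcvp = 100.0 * ddksdp / ddkavp
    ddkjit = 100.0 * float(np.mean(np.abs(np.diff(periods_ms)))) / float(np.mean(periods_ms))
    ddksdi = float(np.std(intensities, ddof=1))
    mean_int = float(np.mean(intensities))
    ddkcvi = 100.0 * ddksdi / mean_int if mean_int > 0 else np.nan
    return DdkFeatures(
        DDKavr=float(ddkavr),
        DDKavp=ddkavp,
        DDKsdp=ddksdp,
        DDKcvp=float(ddkcvp),
        DDKjit=ddkjit,
        DDKsdi=ddksdi,
        DDKcvi=float(ddkcvi),
    )


def _band_envelope(
    rec: AudioRecording, low_hz: float | None, high_hz: float | None, smooth_ms: float = 2.0
) -> np.ndarray:
    """Rectified, lightly smoothed envelope of a band-passed signal (sample rate)."""
    nyq = rec.sample_rate / 2.0
    if low_hz and high_hz:
        b, a = butter(4, [low_hz / nyq, high_hz / nyq], btype="band")
    elif low_hz:
        b, a = butter(4, low_hz / nyq, btype="high")
    else:
        b, a = butter(4, high_hz / nyq, btype="low")
    x = np.abs(filtfilt(b, a, rec.samples))
    bs, as_ = butter(2, (1000.0 / smooth_ms) / nyq)
    return np.maximum(filtfilt(bs, as_, x), 0.0)


def measure_vot(
    rec: AudioRecording,
    events: list[SyllableEvent],
    burst_band_hz: float = 3000.0,
    voicing_band_hz: float = 1000.0,
    threshold_db: float = 12.0,
) -> float:
    """Mean voice onset time (ms) across syllables.

    Per syllable, the burst onset is the first instant the high-band
    (> ``burst_band_hz``) envelope exceeds its noise floor by
    ``threshold_db``; the voicing onset is the analogous crossing of the
    low-band (< ``voicing_band_hz``) envelope, confirmed voiced by the F0
    tracker.  Syllables without a detectable burst or voicing are skipped;
    if none remain the VOT is not computable.
    """
    if not events:
        raise NotComputableError("no syllable events to measure VOT on")
    fs = rec.sample_rate
    hi = _band_envelope(rec, burst_band_hz, None)
    lo = _band_envelope(rec, None, voicing_band_hz)
    hi_floor = np.percentile(hi[hi > 0], 10) if np.any(hi > 0) else 1e-10
    hi_abs = hi_floor * 10 ** (threshold_db / 20.0)
    f0 = track_f0(rec)

    vots = []
    for ev in events:
        w0 = max(0, int((ev.onset_s - 0.080) * fs))
        w1 = min(rec.samples.size, int((ev.peak_s + 0.050) * fs))
        seg_hi = hi[w0:w1]
        if seg_hi.size == 0:
            continue
        # burst onset: first crossing of the larger of (floor + 12 dB) and
        # 15% of this syllable's high-band peak, so vowel harmonics leaking
        # into the high band cannot trigger early
        hi_thresh = max(hi_abs, 0.10 * seg_hi.max())
        if seg_hi.max() <= hi_abs:
            continue
        burst_idx = int(np.argmax(seg_hi > hi_thresh))
        t_burst = (w0 + burst_idx) / fs
        v0 = int(t_burst * fs)
        seg_lo = lo[v0:w1]
        if seg_lo.size == 0 or seg_lo.max() <= 0:
            continue
        # voicing onset: low-band envelope reaching 15% of the vowel's
        # low-band peak (the burst is weak below voicing_band_hz)
        lo_thresh = 0.15 * seg_lo.max()
        voice_idx = int(np.argmax(seg_lo > lo_thresh))
        t_voice = (v0 + voice_idx) / fs
        if t_voice <= t_burst:
            continue
        # require tracker-confirmed voicing shortly after the crossing
        near = (f0.times >= t_voice - 0.02) & (f0.times <= t_voice + 0.08)
        if not np.any(f0.voiced[near]):
            continue
        vots.append((t_voice - t_burst) * 1000.0)
    if not vots:
        raise NotComputableError("no syllable produced both a burst and a voicing onset")
    return float(np.mean(vots))


def analyze_ddk(
    rec: AudioRecording,
    min_prominence: float = 0.1,
    min_period_ms: float = 100.0,
    task_duration_s: float | None = None,
) -> tuple[DdkFeatures, list[SyllableEvent]]:
    """End-to-end DDK analysis: envelope, events, features, VOT.

    ``task_duration_s`` defaults to the recording length (the caller is
    expected to pass trimmed audio).
    """
    env = amplitude_envelope(rec)
    events = detect_syllables(env, min_prominence=min_prominence, min_period_ms=min_period_ms)
    duration = task_duration_s if task_duration_s is not None else rec.duration
    feats = ddk_features(events, duration)
    try:
        vot = measure_vot(rec, events)
    except NotComputableError:
        vot = None
    return DdkFeatures(**{**feats.__dict__, "VOT": vot}), events
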