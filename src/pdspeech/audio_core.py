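"""Audio I/O and the shared DSP primitives for dysarthria feature extraction.

This module owns the two containers every paradigm analysis consumes — an
:class:`AudioRecording` (a mono waveform with task/subject labels) and a
:class:`FrameTrack` (a uniformly hopped per-frame measurement such as an F0
contour) — plus the primitives built on them: band-limited resampling,
amplitude envelope, autocorrelation pitch tracking with voicing decisions,
RMS intensity in dBFS, LPC formant estimation, voiced-segment extraction and
the harmonics-to-noise ratio.

Design notes
------------
The pitch tracker is a normalized-autocorrelation tracker with parabolic
peak interpolation (frame 40 ms, hop 10 ms by default) and a voicing
decision thresholded on the autocorrelation peak height.  Sustained-vowel
analysis in clinical practice tunes such constraints per recording; here
every constraint is an explicit keyword argument so batch runs remain fully
automatic and reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.linalg import solve_toeplitz
from scipy.signal import butter, filtfilt, resample_poly

from .errors import ArgumentError, EmptyInputError, FormatError, NotComputableError

TASKS = ("vowel_a", "vowel_i", "vowel_u", "ddk_pa", "iu_alternation", "passage")

#: Sentinel carried by unvoiced frames in Hz-valued tracks.
UNVOICED = np.nan


@dataclass(frozen=True)
class AudioRecording:
    """A mono waveform normalized to [-1, 1] with protocol labels."""

    samples: np.ndarray
    sample_rate: int
    task: str = "vowel_a"
    subject_id: str = ""
    repetition: int = 1

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ArgumentError("AudioRecording requires a mono (1-D) sample array")
        if samples.size < 1:
            raise EmptyInputError("zero-length audio")
        if not np.all(np.isfinite(samples)):
            raise ArgumentError("audio samples must be finite")
        if self.sample_rate <= 0:
            raise ArgumentError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.task not in TASKS:
            raise ArgumentError(f"unknown task {self.task!r}; expected one of {TASKS}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class FrameTrack:
    """A time-aligned per-frame measurement with voicing flags.

    ``times`` are frame centers in seconds on a uniform hop; unvoiced frames
    carry :data:`UNVOICED` (NaN) in ``values`` for Hz-valued tracks so a
    spurious frequency can never leak into statistics.
    """

    times: np.ndarray
    values: np.ndarray
    voiced: np.ndarray
    frame_length: float
    hop: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        voiced = np.asarray(self.voiced, dtype=bool)
        if not (len(times) == len(values) == len(voiced)):
            raise ArgumentError("times, values and voiced must have equal length")
        if self.hop <= 0:
            raise ArgumentError("hop must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voiced", voiced)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def voiced_values(self) -> np.ndarray:
        return self.values[self.voiced]

    def to_csv(self, path: str | Path) -> None:
        """Write a tidy (time_s, value, voiced) CSV."""
        header = "time_s,value,voiced"
        rows = np.column_stack([self.times, self.values, self.voiced.astype(int)])
        np.savetxt(path, rows, delimiter=",", header=header, comments="", fmt="%.6f")


# ---------------------------------------------------------------------------
# I/O

def read_wav(path: str | Path) -> AudioRecording:
    """Read a RIFF/WAVE PCM file into a mono, [-1, 1]-scaled recording.

    Multi-channel input is averaged to mono with a warning; integer PCM is
    scaled by its full-scale value.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-data chunks are harmless
            rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"not a readable WAV file: {path}: {exc}") from exc
    if data.size == 0:
        raise EmptyInputError(f"zero-length audio in {path}")
    dtype = data.dtype
    is_int = np.issubdtype(dtype, np.integer)
    if np.issubdtype(dtype, np.unsignedinteger):  # 8-bit WAV is offset binary
        half = (np.iinfo(dtype).max + 1) // 2
        data = data.astype(np.int64) - half
        scale = float(half)
    elif is_int:
        scale = float(np.iinfo(dtype).max + 1)
    else:
        scale = 1.0
    if data.ndim == 2:
        warnings.warn(f"{path.name}: averaging {data.shape[1]} channels to mono")
        data = data.mean(axis=1)
    samples = data.astype(np.float64) / scale
    if not is_int:
        samples = np.clip(samples, -1.0, 1.0)
    return AudioRecording(samples=samples, sample_rate=int(rate))


def write_wav(rec: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    wavfile.write(path, rec.sample_rate, np.round(clipped * 32767.0).astype(np.int16))


def resample(rec: AudioRecording, target_rate: int) -> AudioRecording:
    """Band-limited (polyphase) resampling to ``target_rate`` Hz."""
    if target_rate <= 0:
        raise ArgumentError(f"target_rate must be positive, got {target_rate}")
    if target_rate == rec.sample_rate:
        return rec
    frac = Fraction(int(target_rate), int(rec.sample_rate)).limit_denominator(1000)
    out = resample_poly(rec.samples, frac.numerator, frac.denominator)
    return replace(rec, samples=np.clip(out, -1.0, 1.0), sample_rate=int(target_rate))


# ---------------------------------------------------------------------------
# Framing

def _frame_signal(x: np.ndarray, frame_len: int, hop_len: int) -> np.ndarray:
    """Slice ``x`` into overlapping frames (n_frames, frame_len)."""
    if x.size < frame_len:
        return np.empty((0, frame_len))
    n_frames = 1 + (x.size - frame_len) // hop_len
    idx = np.arange(frame_len)[None, :] + hop_len * np.arange(n_frames)[:, None]
    return x[idx]


def _frame_times(n_frames: int, frame_s: float, hop_s: float) -> np.ndarray:
    return frame_s / 2.0 + hop_s * np.arange(n_frames)


# ---------------------------------------------------------------------------
# Envelope and intensity

def amplitude_envelope(
    rec: AudioRecording, smooth_ms: float = 20.0, hop_s: float = 0.005
) -> FrameTrack:
    """Rectified, low-pass-filtered amplitude envelope sampled on a uniform hop.

    The low-pass cutoff is ``1000 / smooth_ms`` Hz, so modulation slower than
    the smoothing window survives (a 20 ms default keeps 7 /s syllable trains
    resolved) while pitch-rate ripple is removed.
    """
    if smooth_ms <= 0:
        raise ArgumentError("smooth_ms must be positive")
    if rec.samples.size == 0:
        raise EmptyInputError("empty recording")
    cutoff = 1000.0 / smooth_ms
    nyq = rec.sample_rate / 2.0
    rectified = np.abs(rec.samples)
    if cutoff < nyq:
        b, a = butter(4, cutoff / nyq)
        pad = min(3 * max(len(a), len(b)), rectified.size - 1)
        smooth = filtfilt(b, a, rectified, padlen=pad)
    else:
        smooth = rectified
    smooth = np.maximum(smooth, 0.0)
    hop_len = max(1, int(round(hop_s * rec.sample_rate)))
    values = smooth[::hop_len]
    times = np.arange(values.size) * (hop_len / rec.sample_rate)
    return FrameTrack(
        times=times,
        values=values,
        voiced=np.ones(values.size, dtype=bool),
        frame_length=smooth_ms / 1000.0,
        hop=hop_len / rec.sample_rate,
    )


def intensity_contour(
    rec: AudioRecording, frame_s: float = 0.04, hop_s: float = 0.01
) -> FrameTrack:
    """Per-frame RMS level in dB re full scale (a full-scale square wave is 0 dBFS)."""
    if rec.samples.size == 0:
        raise EmptyInputError("empty recording")
    frame_len = max(2, int(round(frame_s * rec.sample_rate)))
    hop_len = max(1, int(round(hop_s * rec.sample_rate)))
    frames = _frame_signal(rec.samples, frame_len, hop_len)
    if frames.shape[0] == 0:
        frames = rec.samples[None, : rec.samples.size]
        frame_len = rec.samples.size
    rms = np.sqrt(np.mean(frames**2, axis=1))
    db = 20.0 * np.log10(np.maximum(rms, 1e-10))
    times = _frame_times(frames.shape[0], frame_len / rec.sample_rate, hop_len / rec.sample_rate)
    return FrameTrack(
        times=times,
        values=db,
        voiced=np.ones(frames.shape[0], dtype=bool),
        frame_length=frame_len / rec.sample_rate,
        hop=hop_len / rec.sample_rate,
    )


# ---------------------------------------------------------------------------
# Pitch and HNR

def _autocorr_analysis(
    rec: AudioRecording,
    f0_min: float,
    f0_max: float,
    frame_s: float,
    hop_s: float,
    voicing_threshold: float,
    silence_rms: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Shared framewise normalized-autocorrelation analysis.

    Returns (times, f0, peak_height, voiced, frame_s, hop_s).  ``peak_height``
    is the unbiased normalized autocorrelation at the pitch period — the
    periodicity strength feeding both the voicing decision and the HNR.
    """
    fs = rec.sample_rate
    if not (0 < f0_min < f0_max < fs / 2):
        raise ArgumentError(
            f"need 0 < f0_min < f0_max < fs/2; got ({f0_min}, {f0_max}) at fs={fs}"
        )
    frame_len = int(round(frame_s * fs))
    hop_len = max(1, int(round(hop_s * fs)))
    lag_min = max(2, int(np.floor(fs / f0_max)))
    lag_max = int(np.ceil(fs / f0_min))
    if lag_max >= frame_len:
        raise ArgumentError("frame too short for f0_min; increase frame_s")
    frames = _frame_signal(rec.samples, frame_len, hop_len)
    n = frames.shape[0]
    times = _frame_times(n, frame_len / fs, hop_len / fs)
    if n == 0:
        z = np.zeros(0)
        return times, z, z, z.astype(bool), frame_len / fs, hop_len / fs

    frames = frames - frames.mean(axis=1, keepdims=True)
    r0_raw = np.sum(frames**2, axis=1)
    window = np.hanning(frame_len)
    frames = frames * window
    nfft = 1 << int(np.ceil(np.log2(2 * frame_len)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :frame_len]
    # normalize by the window's own autocorrelation (removes the taper bias,
    # so a perfectly periodic frame peaks near 1 at its period)
    wspec = np.fft.rfft(window, nfft)
    wacf = np.fft.irfft(wspec * np.conj(wspec), nfft)[:frame_len]
    wacf = np.maximum(wacf / wacf[0], 1e-6)
    r0 = acf[:, 0].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = acf / np.maximum(r0[:, None], 1e-30) / wacf[None, :]

    band = norm[:, lag_min : lag_max + 1]
    band_max = band.max(axis=1)
    # prefer the shortest lag among near-maximal candidates to avoid
    # subharmonic (octave-down) errors on strongly periodic frames
    is_cand = band >= np.maximum(0.85 * band_max[:, None], 1e-12)
    interior = np.zeros_like(is_cand)
    interior[:, 1:-1] = (band[:, 1:-1] >= band[:, :-2]) & (band[:, 1:-1] >= band[:, 2:])
    cand = is_cand & interior
    has_cand = cand.any(axis=1)
    first_cand = np.argmax(cand, axis=1)
    peak_rel = np.where(has_cand, first_cand, np.argmax(band, axis=1))
    peak_lag = (peak_rel + lag_min).astype(np.float64)
    peak_val = band[np.arange(n), peak_rel]

    # parabolic interpolation around the integer peak
    can_interp = (peak_lag > lag_min) & (peak_lag < lag_max)
    li = peak_lag.astype(int)
    ym1 = norm[np.arange(n), np.maximum(li - 1, 0)]
    y0 = norm[np.arange(n), li]
    yp1 = norm[np.arange(n), np.minimum(li + 1, frame_len - 1)]
    denom = ym1 - 2 * y0 + yp1
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (ym1 - yp1) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    peak_lag = np.where(can_interp, peak_lag + delta, peak_lag)
    peak_interp = np.where(can_interp, y0 - 0.25 * (ym1 - yp1) * delta, peak_val)

    rms = np.sqrt(np.maximum(r0_raw / frame_len, 0.0))
    voiced = (peak_interp >= voicing_threshold) & (rms > silence_rms)
    f0 = np.where(voiced, fs / peak_lag, UNVOICED)
    f0 = np.where(voiced, np.clip(f0, f0_min, f0_max), f0)
    return times, f0, np.clip(peak_interp, 0.0, 1.0 - 1e-7), voiced, frame_len / fs, hop_len / fs


def track_f0(
    rec: AudioRecording,
    f0_min: float = 75.0,
    f0_max: float = 400.0,
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    voicing_threshold: float = 0.45,
) -> FrameTrack:
    """Autocorrelation F0 contour with per-frame voicing decisions.

    Frames whose normalized-autocorrelation peak falls below
    ``voicing_threshold`` (or whose RMS is at silence level) are flagged
    unvoiced and carry NaN.
    """
    times, f0, _, voiced, flen, hop = _autocorr_analysis(
        rec, f0_min, f0_max, frame_s, hop_s, voicing_threshold
    )
    return FrameTrack(times=times, values=f0, voiced=voiced, frame_length=flen, hop=hop)


def hnr(
    rec: AudioRecording,
    f0_min: float = 75.0,
    f0_max: float = 400.0,
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    voicing_threshold: float = 0.45,
) -> float:
    """Harmonics-to-noise ratio in dB, averaged over voiced frames.

    Per frame, with ``r`` the normalized autocorrelation at the pitch period,
    the harmonic-to-noise power ratio is ``r / (1 - r)`` and the frame HNR is
    ``10·log10(r/(1-r))``; the recording HNR is the mean over voiced frames.
    """
    _, _, strength, voiced, _, _ = _autocorr_analysis(
        rec, f0_min, f0_max, frame_s, hop_s, voicing_threshold
    )
    if not np.any(voiced):
        raise NotComputableError("no voiced frames; HNR undefined")
    r = np.clip(strength[voiced], 1e-7, 1.0 - 1e-7)
    return float(np.mean(10.0 * np.log10(r / (1.0 - r))))


def voicing_segments(f0: FrameTrack, bridge_s: float = 0.05) -> list[tuple[float, float]]:
    """Maximal voiced runs as half-open (start_s, end_s) intervals.

    Unvoiced gaps shorter than ``bridge_s`` are merged, mirroring the manual
    practice of ignoring momentary tracker dropouts inside one phonation.
    """
    voiced = f0.voiced
    if len(voiced) == 0 or not np.any(voiced):
        return []
    segments: list[tuple[float, float]] = []
    half = f0.hop / 2.0
    in_run = False
    start = 0.0
    for i, v in enumerate(voiced):
        if v and not in_run:
            start = f0.times[i] - half
            in_run = True
        elif not v and in_run:
            segments.append((start, f0.times[i - 1] + half))
            in_run = False
    if in_run:
        segments.append((start, f0.times[len(voiced) - 1] + half))
    merged = [segments[0]]
    for s, e in segments[1:]:
        if s - merged[-1][1] < bridge_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(max(0.0, s), e) for s, e in merged]


# ---------------------------------------------------------------------------
# Formants

def lpc_formants(
    rec: AudioRecording,
    n_formants: int = 3,
    frame_s: float = 0.03,
    hop_s: float = 0.01,
    analysis_rate: int = 11000,
    max_bandwidth: float = 400.0,
) -> list[FrameTrack]:
    """Per-frame formant frequencies from LPC polynomial roots.

    The signal is downsampled to ~11 kHz, pre-emphasized, Hamming windowed,
    and fit with an LPC model of order ``2 + fs_kHz`` (the classic rule: one
    pole pair per kHz plus two for spectral tilt).  Roots whose bandwidth
    exceeds ``max_bandwidth`` are rejected as spurious; frames with fewer
    resolvable resonances carry NaN sentinels.
    """
    if not 2 <= n_formants <= 5:
        raise ArgumentError("n_formants must be between 2 and 5")
    work = resample(rec, analysis_rate) if rec.sample_rate > analysis_rate else rec
    fs = work.sample_rate
    x = np.append(work.samples[0], work.samples[1:] - 0.97 * work.samples[:-1])
    frame_len = int(round(frame_s * fs))
    hop_len = max(1, int(round(hop_s * fs)))
    frames = _frame_signal(x, frame_len, hop_len)
    if frames.shape[0] < 2:
        raise EmptyInputError("recording too short for formant analysis (< 2 frames)")
    frames = frames * np.hamming(frame_len)
    order = int(round(2 + fs / 1000.0))

    n = frames.shape[0]
    out = np.full((n, n_formants), np.nan)
    for i in range(n):
        frame = frames[i]
        if np.sqrt(np.mean(frame**2)) < 1e-5:
            continue
        acf = np.correlate(frame, frame, mode="full")[frame_len - 1 : frame_len + order]
        if acf[0] <= 0:
            continue
        try:
            a = solve_toeplitz(acf[:order], acf[1 : order + 1])
        except np.linalg.LinAlgError:
            continue
        roots = np.roots(np.concatenate(([1.0], -a)))
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * fs / (2 * np.pi)
        bws = -fs / np.pi * np.log(np.maximum(np.abs(roots), 1e-12))
        keep = (freqs > 90.0) & (freqs < fs / 2 - 50.0) & (bws < max_bandwidth)
        cand = np.sort(freqs[keep])
        out[i, : min(n_formants, cand.size)] = cand[:n_formants]

    times = _frame_times(n, frame_len / fs, hop_len / fs)
    tracks = []
    for k in range(n_formants):
        vals = out[:, k]
        tracks.append(
            FrameTrack(
                times=times,
                values=vals,
                voiced=~np.isnan(vals),
                frame_length=frame_len / fs,
                hop=hop_len / fs,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Silence trimming

def trim_silence(
    rec: AudioRecording, threshold_db: float = -40.0, smooth_ms: float = 20.0
) -> tuple[AudioRecording, float]:
    """Trim leading/trailing silence relative to the recording's peak envelope.

    Returns the trimmed recording and the trimmed-off lead time in seconds.
    A recording that is entirely below threshold is returned unchanged.
    """
    env = amplitude_envelope(rec, smooth_ms=smooth_ms)
    peak = env.values.max()
    if peak <= 0:
        return rec, 0.0
    active = env.values > peak * 10 ** (threshold_db / 20.0)
    if not np.any(active):
        return rec, 0.0
    idx = np.nonzero(active)[0]
    t0 = env.times[idx[0]]
    t1 = env.times[idx[-1]] + env.hop
    i0 = int(t0 * rec.sample_rate)
    i1 = min(rec.samples.size, int(np.ceil(t1 * rec.sample_rate)))
    return replace(rec, samples=rec.samples[i0:i1]), t0
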