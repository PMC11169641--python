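"""Synthetic speech and cohort generators with exact ground truth.

Every paradigm in the assessment battery (sustained vowels, /pa/
diadochokinesis, /i/-/u/ alternation, passage reading) has a generator here
that emits both a waveform and machine-readable ground truth, so each
measurement stage can be validated by parameter recovery instead of against
unavailable clinical recordings.

The voice source is a Rosenberg-style glottal pulse train passed through
second-order formant resonators.  Realism is deliberately sacrificed for
exactness: the generators are a measurement test bench, not a speech
synthesizer.  Pitch variability is injected as a smoothed per-cycle F0
perturbation normalized to the requested frame-level F0 standard deviation
(white per-cycle jitter would be averaged out within a 40 ms analysis
frame).

Tabular generators (`synth_cohort`, `synth_network`) produce Gaussian
feature cohorts — including a preset parameterized by the published
group means and SDs of all 29 acoustic features — and block-structured node
time series for connectivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .audio_core import AudioRecording
from .errors import ArgumentError

DEFAULT_RATE = 48_000

#: The six features used in the published diagnostic classifier.
SELECTED_FEATURES = ["DDKavr", "NSR", "DPI", "F0std", "F2reg", "VowelArea"]


@dataclass
class SynthesisSpec:
    """Parameters of one synthetic recording; ``seed`` is mandatory."""

    task: str = "vowel_a"
    seed: int = 0
    sample_rate: int = DEFAULT_RATE
    duration_s: float = 7.0
    # phonation
    f0_hz: float = 160.0
    f0_sd_hz: float = 0.0
    amp_cv: float = 0.0
    hnr_db: float = 30.0
    formants: tuple[tuple[float, float], ...] = ((800.0, 80.0), (1300.0, 120.0), (2800.0, 180.0))
    # DDK
    ddk_rate_hz: float = 5.0
    period_cv: float = 0.0
    intensity_cv: float = 0.0
    vot_ms: float = 33.0
    # /i/-/u/
    f2_targets: tuple[float, float] = (2200.0, 800.0)
    alternation_rate_hz: float = 5.0
    # passage
    pause_durations_ms: tuple[float, ...] = ()
    n_syllables: int = 105
    passage_f0_hz: float = 150.0
    passage_f0_sd_hz: float = 30.0


def _rosenberg_cycle(n: int, open_frac: float = 0.4, close_frac: float = 0.16) -> np.ndarray:
    """One glottal-flow cycle of ``n`` samples (Rosenberg C model)."""
    n_open = max(2, int(round(open_frac * n)))
    n_close = max(1, int(round(close_frac * n)))
    pulse = np.zeros(n)
    t = np.arange(n_open)
    pulse[:n_open] = 0.5 * (1.0 - np.cos(np.pi * t / n_open))
    t = np.arange(n_close)
    stop = min(n, n_open + n_close)
    pulse[n_open:stop] = np.cos(np.pi * t[: stop - n_open] / (2 * n_close))
    return pulse


def _resonator_coeffs(freq: float, bw: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    r = np.exp(-np.pi * bw / fs)
    theta = 2.0 * np.pi * freq / fs
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    b = np.array([1.0 - r])
    return b, a


def _apply_formants(x: np.ndarray, formants, fs: float) -> np.ndarray:
    for freq, bw in formants:
        b, a = _resonator_coeffs(freq, bw, fs)
        x = lfilter(b, a, x)
    return x


def _smoothed_unit_noise(rng: np.random.Generator, n: int, span: int) -> np.ndarray:
    """Moving-average-smoothed Gaussian noise renormalized to unit SD."""
    if n == 0:
        return np.zeros(0)
    e = rng.standard_normal(n + span)
    kernel = np.ones(span) / span
    sm = np.convolve(e, kernel, mode="same")[:n]
    sd = sm.std()
    return sm / sd if sd > 0 else np.zeros(n)


def _pulse_train(
    rng: np.random.Generator,
    fs: int,
    duration_s: float,
    f0_hz: float,
    f0_sd_hz: float,
    amp_cv: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Glottal source with per-cycle F0/amplitude perturbation.

    Returns (waveform, per-cycle F0 values actually used).
    """
    n_total = int(round(duration_s * fs))
    n_cycles = int(np.ceil(duration_s * (f0_hz + 4 * f0_sd_hz))) + 4
    # smooth over ~8 cycles so the perturbation survives frame-level analysis
    f0_per_cycle = f0_hz + f0_sd_hz * _smoothed_unit_noise(rng, n_cycles, 8)
    f0_per_cycle = np.clip(f0_per_cycle, f0_hz * 0.5, f0_hz * 1.8)
    amps = 1.0 + amp_cv * _smoothed_unit_noise(rng, n_cycles, 8)
    amps = np.clip(amps, 0.1, None)

    out = np.zeros(n_total)
    pos = 0
    used_f0 = []
    for k in range(n_cycles):
        period = int(round(fs / f0_per_cycle[k]))
        if pos + period > n_total:
            break
        out[pos : pos + period] = amps[k] * _rosenberg_cycle(period)
        used_f0.append(fs / period)
        pos += period
    return out, np.asarray(used_f0)


def _mix_noise(rng: np.random.Generator, voiced: np.ndarray, hnr_db: float, fs: int,
               formants=None) -> np.ndarray:
    """Add noise at the given harmonics-to-noise power ratio (skip above 60 dB)."""
    if hnr_db >= 60.0:
        return voiced
    p_voiced = np.mean(voiced**2)
    if p_voiced <= 0:
        raise ArgumentError("cannot set an HNR on a silent signal")
    noise = rng.standard_normal(voiced.size)
    if formants is not None:
        noise = _apply_formants(noise, formants, fs)
    p_noise_target = p_voiced / (10.0 ** (hnr_db / 10.0))
    noise *= np.sqrt(p_noise_target / np.mean(noise**2))
    return voiced + noise


def _normalize(x: np.ndarray, peak: float = 0.5) -> np.ndarray:
    m = np.max(np.abs(x))
    return x * (peak / m) if m > 0 else x


# ---------------------------------------------------------------------------
# Audio generators

def synth_vowel(spec: SynthesisSpec) -> tuple[AudioRecording, dict]:
    """Sustained-vowel synthesis with controlled F0, F0 SD, amplitude CV and HNR."""
    if not spec.task.startswith("vowel"):
        raise ArgumentError(f"synth_vowel requires a vowel task, got {spec.task!r}")
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    source, cycle_f0 = _pulse_train(
        rng, fs, spec.duration_s, spec.f0_hz, spec.f0_sd_hz, spec.amp_cv
    )
    voiced = _apply_formants(source - source.mean(), spec.formants, fs)
    # aspiration noise follows the formant envelope (wide-bandwidth copies of
    # the resonators): spectrally realistic, yet its autocorrelation decays
    # well before the pitch period so the HNR calibration stays exact
    wide = tuple((f, 4.0 * bw) for f, bw in spec.formants)
    mixed = _mix_noise(rng, voiced, spec.hnr_db, fs, formants=wide)
    rec = AudioRecording(_normalize(mixed), fs, task=spec.task)
    truth = {
        "f0_hz": spec.f0_hz,
        "f0_sd_hz": spec.f0_sd_hz,
        "amp_cv": spec.amp_cv,
        "hnr_db": spec.hnr_db,
        "formants": [f for f, _ in spec.formants],
        "cycle_f0": cycle_f0,
        "duration_s": spec.duration_s,
    }
    return rec, truth


def synth_ddk(spec: SynthesisSpec) -> tuple[AudioRecording, list[dict]]:
    """Fast /pa/ train: per syllable a VOT burst then a short voiced vowel.

    Inter-syllable periods are drawn with CV ``period_cv`` and peak amplitudes
    with CV ``intensity_cv``; ground-truth events (onset, voicing onset, peak
    amplitude, period) are returned alongside the audio.  A low-level
    low-frequency ambient floor spans the task so the active task duration
    equals ``duration_s``.
    """
    if not 2.0 <= spec.ddk_rate_hz <= 9.0:
        raise ArgumentError("ddk_rate_hz must lie in [2, 9] syllables/s")
    n_syl = int(round(spec.ddk_rate_hz * spec.duration_s))
    if n_syl < 3:
        raise ArgumentError("rate x duration must yield at least 3 syllables")
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    n_total = int(round(spec.duration_s * fs))
    out = np.zeros(n_total)

    base_period = 1.0 / spec.ddk_rate_hz
    periods = base_period * (1.0 + spec.period_cv * rng.standard_normal(n_syl))
    periods = np.clip(periods, 0.4 * base_period, 2.0 * base_period)
    # rescale so the n syllables exactly tile the task duration
    periods *= spec.duration_s / periods.sum()
    onsets = np.concatenate([[0.0], np.cumsum(periods[:-1])])
    amps = np.clip(1.0 + spec.intensity_cv * rng.standard_normal(n_syl), 0.2, None)

    vot_s = spec.vot_ms / 1000.0
    vowel_len = min(0.10, 0.55 * base_period)
    f0_vowel = 140.0
    events = []
    for k in range(n_syl):
        t0 = onsets[k]
        i0 = int(round(t0 * fs))
        # burst: band-limited noise above 3 kHz
        nb = int(round(vot_s * fs))
        burst = rng.standard_normal(nb)
        burst = np.diff(np.concatenate([[0.0], burst]))  # high-pass tilt
        burst *= 0.18 * amps[k] * np.hanning(nb)
        # vowel: short voiced segment with fast attack
        src, _ = _pulse_train(rng, fs, vowel_len, f0_vowel, 0.0, 0.0)
        vowel = _apply_formants(src - src.mean(), ((800.0, 90.0), (1250.0, 110.0)), fs)
        m = np.max(np.abs(vowel))
        if m > 0:
            vowel = vowel / m * amps[k]
        nv = vowel.size
        # fast attack to a unique early peak, then a smooth decay: voicing
        # onsets stay sharp for VOT while peak-to-peak periods stay stable
        n_pk = min(int(0.015 * fs), nv // 3)
        t_up = np.arange(n_pk)
        t_dn = np.arange(nv - n_pk)
        window = np.concatenate(
            [
                np.sin(0.5 * np.pi * (t_up + 1) / n_pk) ** 2,
                np.cos(0.5 * np.pi * t_dn / (nv - n_pk)) ** 1.5,
            ]
        )
        vowel *= window
        iv = i0 + nb
        seg_end = min(n_total, iv + nv)
        if i0 + nb <= n_total:
            out[i0 : i0 + nb] += burst[: max(0, min(nb, n_total - i0))]
        if iv < n_total:
            out[iv:seg_end] += vowel[: seg_end - iv]
        events.append(
            {
                "onset_s": t0,
                "voicing_onset_s": t0 + vot_s,
                "peak_amp": amps[k],
                "period_s": periods[k],
                "vot_ms": spec.vot_ms,
            }
        )
    # ambient low-frequency floor spanning the task (~-36 dB re peak)
    b, a = _resonator_coeffs(200.0, 400.0, fs)
    ambient = lfilter(b, a, rng.standard_normal(n_total))
    ambient *= (0.016 * np.max(np.abs(out))) / max(np.std(ambient), 1e-12)
    out += ambient
    rec = AudioRecording(_normalize(out), fs, task="ddk_pa")
    return rec, events


def synth_iu(spec: SynthesisSpec) -> tuple[AudioRecording, list[dict]]:
    """/i/-/u/ alternation: a voiced carrier whose F2 sweeps between targets.

    The second-formant trajectory is a piecewise cosine alternating between
    ``f2_targets`` (high = /i/, low = /u/), one cycle per alternation, with
    per-cycle period CV ``period_cv``.  Ground truth lists each cycle's peak
    and trough times and the F2 targets.
    """
    hi, lo = spec.f2_targets
    if hi <= lo:
        raise ArgumentError("f2_targets must be (high, low) with high > low")
    if spec.alternation_rate_hz <= 0:
        raise ArgumentError("alternation_rate_hz must be positive")
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    n_total = int(round(spec.duration_s * fs))

    n_cycles = int(round(spec.alternation_rate_hz * spec.duration_s))
    base_period = 1.0 / spec.alternation_rate_hz
    periods = base_period * (1.0 + spec.period_cv * rng.standard_normal(n_cycles))
    periods = np.clip(periods, 0.4 * base_period, 2.0 * base_period)
    periods *= spec.duration_s / periods.sum()

    # instantaneous F2: smoothed trapezoid per cycle — dwell on /i/ (high),
    # transition, dwell on /u/ (low), transition back; vowel dwells mirror
    # real alternation and give the formant tracker stable targets
    f2 = np.empty(n_total)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    truth = []
    for k in range(n_cycles):
        i0 = int(round(starts[k] * fs))
        i1 = min(n_total, int(round(starts[k + 1] * fs)))
        n = i1 - i0
        if n <= 0:
            continue
        phase = np.arange(n) / n  # cycle phase in [0, 1)
        shape = np.empty(n)
        dwell, trans = 0.30, 0.20
        m_hi = phase < dwell
        m_dn = (phase >= dwell) & (phase < dwell + trans)
        m_lo = (phase >= dwell + trans) & (phase < 2 * dwell + trans)
        m_up = phase >= 2 * dwell + trans
        shape[m_hi] = 1.0
        shape[m_dn] = 0.5 * (1 + np.cos(np.pi * (phase[m_dn] - dwell) / trans))
        shape[m_lo] = 0.0
        shape[m_up] = 0.5 * (1 - np.cos(np.pi * (phase[m_up] - 2 * dwell - trans) / trans))
        f2[i0:i1] = lo + (hi - lo) * shape
        truth.append(
            {
                "peak_time_s": starts[k] + 0.15 * periods[k],
                "trough_time_s": starts[k] + 0.55 * periods[k],
                "f2_peak": hi,
                "f2_trough": lo,
                "cycle_period_s": periods[k],
            }
        )
    if n_cycles:
        f2[i1:] = f2[i1 - 1] if i1 > 0 else hi

    def vocal_tract(excitation: np.ndarray) -> np.ndarray:
        """Static F1/F3/F4 resonators plus the per-sample time-varying F2."""
        x = excitation - excitation.mean()
        for freq, bw in ((330.0, 70.0), (2900.0, 200.0), (3900.0, 250.0)):
            b, a = _resonator_coeffs(freq, bw, fs)
            x = lfilter(b, a, x)
        r = np.exp(-np.pi * 90.0 / fs)
        cos_t = 2.0 * r * np.cos(2.0 * np.pi * f2[: x.size] / fs)
        r2, gain = r * r, 1.0 - r
        y = np.empty(x.size)
        y1 = y2 = 0.0
        for i in range(x.size):
            y0 = gain * x[i] + cos_t[i] * y1 - r2 * y2
            y[i] = y0
            y2, y1 = y1, y0
        return y

    src, _ = _pulse_train(rng, fs, spec.duration_s, 120.0, 0.0, 0.0)
    voiced = vocal_tract(src)
    out = voiced
    if spec.hnr_db < 60.0:
        # aspiration noise shaped by the same vocal tract, so the spectral
        # envelope (and hence formant tracking) survives the mixing
        noise = vocal_tract(rng.standard_normal(n_total))
        p_noise = np.mean(voiced**2) / (10.0 ** (spec.hnr_db / 10.0))
        out = voiced + noise * np.sqrt(p_noise / np.mean(noise**2))
    rec = AudioRecording(_normalize(out), fs, task="iu_alternation")
    return rec, truth


def synth_passage(spec: SynthesisSpec) -> tuple[AudioRecording, dict]:
    """Passage-reading proxy: voiced syllable train interleaved with known pauses.

    ``n_syllables`` equal-length voiced syllables fill the non-pause time of
    ``duration_s``; the silent pauses in ``pause_durations_ms`` are inserted at
    evenly spaced syllable boundaries.  Per-syllable F0 is drawn around
    ``passage_f0_hz`` with SD ``passage_f0_sd_hz``.  Ground truth carries the
    exact pause intervals, net speech time and F0 schedule.
    """
    if spec.n_syllables < 1:
        raise ArgumentError("n_syllables must be >= 1")
    pauses_s = [p / 1000.0 for p in spec.pause_durations_ms]
    if any(p < 0 for p in pauses_s):
        raise ArgumentError("pause durations must be nonnegative")
    net_s = spec.duration_s - sum(pauses_s)
    if net_s <= 0:
        raise ArgumentError("pauses exceed the requested duration")
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    syl_len = net_s / spec.n_syllables
    n_pause = len(pauses_s)
    # insert pause j after syllable boundary positions spread through the text
    after = (
        [int(round((j + 1) * spec.n_syllables / (n_pause + 1))) for j in range(n_pause)]
        if n_pause
        else []
    )

    f0s = rng.normal(spec.passage_f0_hz, spec.passage_f0_sd_hz, spec.n_syllables)
    f0s = np.clip(f0s, 80.0, 350.0)
    pieces: list[np.ndarray] = []
    t = 0.0
    pause_truth = []
    n_ramp = int(0.008 * fs)
    for k in range(spec.n_syllables):
        src, _ = _pulse_train(rng, fs, syl_len, float(f0s[k]), 0.0, 0.0)
        syl = _apply_formants(src - src.mean(), ((700.0, 90.0), (1400.0, 120.0)), fs)
        m = np.max(np.abs(syl))
        if m > 0:
            syl /= m
        if syl.size > 2 * n_ramp:
            syl[:n_ramp] *= np.linspace(0, 1, n_ramp)
            syl[-n_ramp:] *= np.linspace(1, 0, n_ramp)
        pieces.append(syl)
        t += syl.size / fs
        if k + 1 in after:
            j = after.index(k + 1)
            n_sil = int(round(pauses_s[j] * fs))
            pause_truth.append((t, t + n_sil / fs))
            pieces.append(np.zeros(n_sil))
            t += n_sil / fs
    samples = np.concatenate(pieces)
    rec = AudioRecording(_normalize(samples), fs, task="passage")
    truth = {
        "pauses": pause_truth,
        "net_speech_s": net_s,
        "total_s": samples.size / fs,
        "n_syllables": spec.n_syllables,
        "f0_per_syllable": f0s,
        "f0_hz": spec.passage_f0_hz,
        "f0_sd_hz": spec.passage_f0_sd_hz,
    }
    return rec, truth


# ---------------------------------------------------------------------------
# Tabular generators

def reference_feature_params() -> pd.DataFrame:
    """Published group means and SDs of the 29 acoustic features.

    Columns: feature, hc_mean, hc_sd, pd_mean, pd_sd.  These parameterize the
    default synthetic cohort (n = 40 controls / 80 patients).
    """
    with resources.files("pdspeech.data").joinpath("feature_params.csv").open() as fh:
        return pd.read_csv(fh)


_HY_LEVELS = np.array([1.5, 2.0, 2.5, 3.0, 4.0, 5.0])
_HY_PROBS = np.array([0.08, 0.17, 0.25, 0.32, 0.12, 0.06])


def synth_cohort(
    n_hc: int = 40,
    n_pd: int = 80,
    params: pd.DataFrame | None = None,
    sex_ratio_hc: float = 18 / 40,
    sex_ratio_pd: float = 45 / 80,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian synthetic cohort with independent feature draws per group.

    ``params`` defaults to :func:`reference_feature_params`.  Covariates (age,
    height, weight, MoCA) are drawn from the published cohort's ranges;
    disease-stage and UPDRS columns are filled for patients only.
    """
    if n_hc < 2 or n_pd < 2:
        raise ArgumentError("need at least 2 subjects per group")
    if params is None:
        params = reference_feature_params()
    for col in ("feature", "hc_mean", "hc_sd", "pd_mean", "pd_sd"):
        if col not in params.columns:
            raise ArgumentError(f"params is missing column {col!r}")
    if (params[["hc_sd", "pd_sd"]] < 0).any().any():
        raise ArgumentError("feature SDs must be nonnegative")
    rng = np.random.default_rng(seed)
    n = n_hc + n_pd
    group = np.array(["HC"] * n_hc + ["PD"] * n_pd)
    sex = np.concatenate(
        [
            np.where(rng.random(n_hc) < sex_ratio_hc, "M", "F"),
            np.where(rng.random(n_pd) < sex_ratio_pd, "M", "F"),
        ]
    )
    age = np.concatenate(
        [
            np.clip(rng.normal(60.68, 8.11, n_hc), 45, 77),
            np.clip(rng.normal(62.34, 8.87, n_pd), 44, 80),
        ]
    )
    height = np.concatenate(
        [
            np.clip(rng.normal(164.23, 7.10, n_hc), 150, 182),
            np.clip(rng.normal(166.26, 7.92, n_pd), 150, 185),
        ]
    )
    weight = np.concatenate(
        [
            np.clip(rng.normal(67.70, 9.97, n_hc), 48, 88),
            np.clip(rng.normal(66.42, 11.66, n_pd), 45, 96),
        ]
    )
    moca = np.concatenate(
        [
            np.clip(np.round(rng.normal(25.68, 1.27, n_hc)), 24, 29),
            np.clip(np.round(rng.normal(23.73, 3.71, n_pd)), 16, 30),
        ]
    )
    handed = np.where(rng.random(n) < 0.9, "R", "L")

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "group": group,
            "sex": sex,
            "age": np.round(age, 1),
            "height": np.round(height, 1),
            "weight": np.round(weight, 1),
            "MoCA": moca,
            "handedness": handed,
        }
    )
    hy = rng.choice(_HY_LEVELS, size=n_pd, p=_HY_PROBS)
    df["HY_stage"] = np.concatenate([np.full(n_hc, np.nan), hy])
    df["UPDRS_III"] = np.concatenate(
        [np.full(n_hc, np.nan), np.clip(np.round(rng.normal(45.56, 17.96, n_pd)), 10, 91)]
    )
    df["UPDRS_speech"] = np.concatenate(
        [np.full(n_hc, np.nan), np.clip(np.round(rng.normal(1.09, 0.83, n_pd)), 0, 3)]
    )
    df["UPDRS_bradykinesia"] = np.concatenate(
        [np.full(n_hc, np.nan), np.clip(np.round(rng.normal(20.0, 8.0, n_pd)), 0, 40)]
    )
    df["UPDRS_tremor"] = np.concatenate(
        [np.full(n_hc, np.nan), np.clip(np.round(rng.normal(6.0, 4.0, n_pd)), 0, 24)]
    )

    is_pd = group == "PD"
    for _, row in params.iterrows():
        vals = np.where(
            is_pd,
            rng.normal(row["pd_mean"], row["pd_sd"], n),
            rng.normal(row["hc_mean"], row["hc_sd"], n),
        )
        df[row["feature"]] = vals
    return df


def synth_network(
    n_nodes: int = 90,
    n_timepoints: int = 200,
    block_structure: tuple[int, ...] | int = 3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Block-structured node time series: shared latent signal plus noise.

    Returns (series, labels) where ``series`` is n_nodes x n_timepoints and
    ``labels[i]`` is node i's block index; within-block correlation exceeds
    between-block correlation by construction.
    """
    if n_nodes < 2 or n_timepoints < 10:
        raise ArgumentError("need n_nodes >= 2 and n_timepoints >= 10")
    rng = np.random.default_rng(seed)
    if isinstance(block_structure, int):
        base = n_nodes // block_structure
        sizes = [base] * block_structure
        sizes[-1] += n_nodes - base * block_structure
    else:
        sizes = list(block_structure)
        if sum(sizes) != n_nodes:
            raise ArgumentError("block sizes must sum to n_nodes")
    labels = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
    latents = rng.standard_normal((len(sizes), n_timepoints))
    series = latents[labels] + noise_sd * rng.standard_normal((n_nodes, n_timepoints))
    return series, labels
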