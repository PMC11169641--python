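"""Unit tests for the shared DSP primitives."""

import numpy as np
import pytest
from scipy.io import wavfile

import pdspeech as pk
from pdspeech.audio_core import AudioRecording, FrameTrack
from pdspeech.errors import ArgumentError, EmptyInputError, FormatError, NotComputableError

FS = 48_000


def _sine(freq, duration=1.0, amp=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return AudioRecording(amp * np.sin(2 * np.pi * freq * t), fs)


class TestReadWriteWav:
    def test_silence_round_trip(self, tmp_path):
        path = tmp_path / "silence.wav"
        wavfile.write(path, FS, np.zeros(FS, dtype=np.int16))
        rec = pk.read_wav(path)
        assert rec.sample_rate == FS
        assert rec.samples.shape == (FS,)
        assert np.all(rec.samples == 0.0)

    def test_stereo_identical_channels_average_to_mono(self, tmp_path):
        mono = (np.sin(2 * np.pi * 440 * np.arange(FS) / FS) * 20000).astype(np.int16)
        path = tmp_path / "stereo.wav"
        wavfile.write(path, FS, np.column_stack([mono, mono]))
        rec = pk.read_wav(path)
        np.testing.assert_allclose(rec.samples, mono / 32768.0, atol=1e-9)

    def test_write_read_round_trip_sine(self, tmp_path):
        rec = _sine(440.0, amp=0.8)
        path = tmp_path / "sine.wav"
        pk.write_wav(rec, path)
        back = pk.read_wav(path)
        assert np.max(np.abs(back.samples - rec.samples)) < 2**-14

    def test_not_a_wav_raises_format_error(self, tmp_path):
        path = tmp_path / "junk.wav"
        path.write_bytes(b"this is not RIFF data at all")
        with pytest.raises(FormatError):
            pk.read_wav(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FormatError):
            pk.read_wav(tmp_path / "absent.wav")


class TestResample:
    def test_identity_when_rate_matches(self):
        rec = _sine(440.0)
        assert pk.resample(rec, FS) is rec

    def test_round_trip_preserves_waveform(self):
        rec = _sine(1000.0)
        back = pk.resample(pk.resample(rec, 16_000), FS)
        n = min(back.samples.size, rec.samples.size)
        a, b = back.samples[:n], rec.samples[:n]
        corr = np.corrcoef(a, b)[0, 1]
        assert corr > 0.999

    @pytest.mark.parametrize("target", [8000, 11025, 16000, 44100])
    def test_duration_conserved(self, target):
        rec = _sine(200.0, duration=1.0)
        out = pk.resample(rec, target)
        assert abs(out.samples.size - target) <= 1

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ArgumentError):
            pk.resample(_sine(200.0), 0)


class TestAmplitudeEnvelope:
    def test_constant_sine_envelope_flat(self):
        rec = _sine(200.0, duration=1.0, amp=0.5)
        env = pk.amplitude_envelope(rec, smooth_ms=20.0)
        inner = env.values[(env.times > 0.1) & (env.times < 0.9)]
        # rectified-sine mean is 2/pi of the peak; tolerance 10% of 0.5
        assert np.all(np.abs(inner - np.mean(inner)) < 0.05)
        assert np.all(env.values >= 0)

    def test_silence_gives_zeros(self):
        rec = AudioRecording(np.zeros(FS), FS)
        env = pk.amplitude_envelope(rec)
        assert np.allclose(env.values, 0.0, atol=1e-12)

    def test_am_modulation_peak_count(self):
        t = np.arange(2 * FS) / FS
        carrier = np.sin(2 * np.pi * 300 * t)
        modulated = (0.55 + 0.45 * np.sin(2 * np.pi * 4 * t)) * carrier
        env = pk.amplitude_envelope(AudioRecording(modulated, FS), smooth_ms=20.0)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(env.values, prominence=0.2 * env.values.max())
        assert abs(len(peaks) - 8) <= 1  # 4 Hz x 2 s


class TestTrackF0:
    def test_recovers_vowel_f0(self, vowel_160):
        rec, _ = vowel_160
        track = pk.track_f0(rec)
        mean_f0 = np.mean(track.voiced_values)
        assert 158.4 <= mean_f0 <= 161.6

    def test_white_noise_mostly_unvoiced(self):
        rng = np.random.default_rng(0)
        rec = AudioRecording(0.3 * rng.standard_normal(FS), FS)
        track = pk.track_f0(rec)
        assert track.voiced.mean() < 0.20

    def test_glide_follows_schedule(self):
        t = np.arange(2 * FS) / FS
        inst_freq = 120.0 + 30.0 * t  # 120 -> 180 Hz over 2 s
        phase = 2 * np.pi * np.cumsum(inst_freq) / FS
        rec = AudioRecording(0.7 * np.sign(np.sin(phase)) * 0.5, FS)
        track = pk.track_f0(rec)
        target = np.interp(track.times, t, inst_freq)
        err = track.values[track.voiced] - target[track.voiced]
        assert np.percentile(np.abs(err), 95) < 3.0

    def test_gain_invariance(self, vowel_160):
        rec, _ = vowel_160
        half = AudioRecording(rec.samples * 0.5, rec.sample_rate)
        a = pk.track_f0(rec)
        b = pk.track_f0(half)
        np.testing.assert_allclose(a.voiced_values.mean(), b.voiced_values.mean(), atol=0.2)

    def test_impossible_range_rejected(self, vowel_160):
        rec, _ = vowel_160
        with pytest.raises(ArgumentError):
            pk.track_f0(rec, f0_min=400, f0_max=75)

    def test_time_shift_equivariance(self, ddk_rate5):
        rec, _ = ddk_rate5
        shifted = AudioRecording(
            np.concatenate([np.zeros(int(0.1 * rec.sample_rate)), rec.samples]),
            rec.sample_rate,
            task=rec.task,
        )
        env_a = pk.amplitude_envelope(rec)
        env_b = pk.amplitude_envelope(shifted)
        ev_a = pk.detect_syllables(env_a)
        ev_b = pk.detect_syllables(env_b)
        assert len(ev_a) == len(ev_b)
        shifts = [b.peak_s - a.peak_s for a, b in zip(ev_a, ev_b)]
        assert np.allclose(shifts, 0.100, atol=env_a.hop + 1e-9)


class TestIntensityContour:
    def test_full_scale_square_is_zero_dbfs(self):
        rec = AudioRecording(np.sign(np.sin(2 * np.pi * 100 * np.arange(FS) / FS)), FS)
        track = pk.intensity_contour(rec)
        assert np.all(np.abs(track.values) < 0.1)

    def test_gain_law_six_db(self):
        rec = _sine(200.0, amp=0.8)
        half = AudioRecording(rec.samples * 0.5, FS)
        a = pk.intensity_contour(rec).values
        b = pk.intensity_contour(half).values
        np.testing.assert_allclose(a - b, 6.02, atol=0.1)

    def test_sine_amplitude_point_one(self):
        rec = _sine(200.0, amp=0.1)
        track = pk.intensity_contour(rec)
        np.testing.assert_allclose(track.values, 20 * np.log10(0.1 / np.sqrt(2)), atol=0.5)


class TestLpcFormants:
    def test_two_resonator_recovery(self):
        spec = pk.SynthesisSpec(
            task="vowel_a", seed=5, duration_s=2.0, f0_hz=110.0,
            formants=((300.0, 60.0), (2200.0, 150.0)), hnr_db=25.0,
        )
        rec, _ = pk.synth_vowel(spec)
        f1, f2 = pk.lpc_formants(rec, n_formants=2)
        assert 270 <= np.nanmedian(f1.values) <= 330
        assert 2100 <= np.nanmedian(f2.values) <= 2300

    def test_low_pair_recovery_within_ten_percent(self):
        spec = pk.SynthesisSpec(
            task="vowel_a", seed=6, duration_s=2.0, f0_hz=120.0,
            formants=((800.0, 80.0), (1200.0, 100.0)), hnr_db=60.0,
        )
        rec, _ = pk.synth_vowel(spec)
        f1, f2 = pk.lpc_formants(rec, n_formants=2)
        assert abs(np.nanmedian(f1.values) - 800) < 80
        assert abs(np.nanmedian(f2.values) - 1200) < 120

    def test_ascending_order_invariant(self, vowel_160):
        rec, _ = vowel_160
        tracks = pk.lpc_formants(rec, n_formants=3)
        stacked = np.stack([t.values for t in tracks])
        for frame in stacked.T:
            defined = frame[np.isfinite(frame)]
            assert np.all(np.diff(defined) > 0)

    def test_too_short_input_rejected(self):
        rec = AudioRecording(np.ones(64) * 0.1, FS)
        with pytest.raises(EmptyInputError):
            pk.lpc_formants(rec)


class TestVoicingSegmentsAndHnr:
    def test_all_voiced_single_segment(self):
        track = FrameTrack(
            times=0.02 + 0.01 * np.arange(300),
            values=np.full(300, 150.0),
            voiced=np.ones(300, dtype=bool),
            frame_length=0.04,
            hop=0.01,
        )
        segs = pk.voicing_segments(track)
        assert len(segs) == 1
        assert segs[0][1] - segs[0][0] == pytest.approx(3.0, abs=0.05)

    def test_no_voiced_frames_empty(self):
        track = FrameTrack(
            times=0.02 + 0.01 * np.arange(10),
            values=np.full(10, np.nan),
            voiced=np.zeros(10, dtype=bool),
            frame_length=0.04,
            hop=0.01,
        )
        assert pk.voicing_segments(track) == []

    def test_bridge_merges_short_gap(self):
        voiced = np.ones(200, dtype=bool)
        voiced[100:102] = False  # 20 ms gap < 50 ms bridge
        track = FrameTrack(
            times=0.02 + 0.01 * np.arange(200),
            values=np.where(voiced, 150.0, np.nan),
            voiced=voiced,
            frame_length=0.04,
            hop=0.01,
        )
        assert len(pk.voicing_segments(track, bridge_s=0.05)) == 1
        assert len(pk.voicing_segments(track, bridge_s=0.005)) == 2

    def test_clean_vowel_high_hnr(self):
        rec, _ = pk.synth_vowel(
            pk.SynthesisSpec(task="vowel_a", seed=8, duration_s=3.0, f0_hz=160.0, hnr_db=60.0)
        )
        assert pk.hnr(rec) > 25.0

    def test_noise_alone_not_computable_or_low(self):
        rng = np.random.default_rng(1)
        rec = AudioRecording(0.3 * rng.standard_normal(2 * FS), FS)
        try:
            value = pk.hnr(rec)
        except NotComputableError:
            return
        assert value < 3.0

    def test_ten_to_one_power_ratio(self):
        rec, _ = pk.synth_vowel(
            pk.SynthesisSpec(task="vowel_a", seed=9, duration_s=4.0, f0_hz=160.0, hnr_db=10.0)
        )
        assert pk.hnr(rec) == pytest.approx(10.0, abs=1.5)

    def test_gain_invariance(self, vowel_160):
        rec, _ = vowel_160
        half = AudioRecording(rec.samples * 0.5, rec.sample_rate)
        assert pk.hnr(rec) == pytest.approx(pk.hnr(half), abs=0.5)
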