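"""Shared synthetic fixtures (session-scoped: synthesis is the slow part)."""

import warnings

import pytest

import pdspeech as pk


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def vowel_160():
    """Clean sustained /a/ at 160 Hz, no jitter, HNR 30 dB, 5 s."""
    spec = pk.SynthesisSpec(
        task="vowel_a", seed=11, duration_s=5.0, f0_hz=160.0,
        f0_sd_hz=0.0, amp_cv=0.0, hnr_db=30.0,
    )
    return pk.synth_vowel(spec)


@pytest.fixture(scope="session")
def ddk_rate5():
    """Uniform /pa/ train at 5 syllables/s for 7 s."""
    spec = pk.SynthesisSpec(task="ddk_pa", seed=21, duration_s=7.0, ddk_rate_hz=5.0)
    return pk.synth_ddk(spec)


@pytest.fixture(scope="session")
def iu_rate5():
    """/i/-/u/ alternation at 5 cycles/s, targets 2200/800 Hz, 5 s."""
    spec = pk.SynthesisSpec(
        task="iu_alternation", seed=31, duration_s=5.0,
        alternation_rate_hz=5.0, f2_targets=(2200.0, 800.0), hnr_db=25.0,
    )
    return pk.synth_iu(spec)


@pytest.fixture(scope="session")
def passage_std():
    """105-syllable passage proxy: 24 s total with six 500 ms pauses (net 21 s)."""
    spec = pk.SynthesisSpec(
        task="passage", seed=41, duration_s=24.0,
        pause_durations_ms=(500.0,) * 6, n_syllables=105,
    )
    return pk.synth_passage(spec)


@pytest.fixture(scope="session")
def cohort_table():
    """Default synthetic cohort (n = 40 HC / 80 PD) at the reference parameters."""
    return pk.synth_cohort(seed=7)
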