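import numpy as np
import pytest

from parkfuse.synthetic import SAMPLE_RATE, SubjectProfile, SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small shared-mode corpus with a strong class effect."""
    return generate_corpus(
        SynthConfig(
            n_subjects_per_class=6,
            utterances_per_subject=2,
            duration_s=1.0,
            effect_size=2.0,
            coupling_mode="shared",
            seed=123,
        )
    )


@pytest.fixture(scope="session")
def vowel():
    """Two seconds of a synthetic vowel-like harmonic tone at 150 Hz."""
    t = np.arange(2 * SAMPLE_RATE) / SAMPLE_RATE
    x = (
        np.sin(2 * np.pi * 150 * t)
        + 0.4 * np.sin(2 * np.pi * 300 * t)
        + 0.15 * np.sin(2 * np.pi * 900 * t)
    )
    return 0.8 * x / np.abs(x).max()


@pytest.fixture(scope="session")
def vowel_silence_vowel(vowel):
    """Vowel, half a second of silence, vowel: one offset and one onset."""
    half = len(vowel) // 2
    return np.concatenate([vowel[:half], np.zeros(SAMPLE_RATE // 2), vowel[:half]])


@pytest.fixture(scope="session")
def hc_profile():
    return SubjectProfile(
        subject_id="HC000",
        label="HC",
        modulation_depth=0.75,
        jitter_level=0.01,
        pause_rate=0.3,
        base_f0=150.0,
    )
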