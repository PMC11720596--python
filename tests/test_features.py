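"""Classical speech feature tests: F0, transitions, perturbation measures,
and the 488/28/103 dimensional contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parkfuse.features import (
    ARTICULATION_DIM,
    PHONATION_DIM,
    PROSODY_DIM,
    articulation_feature_names,
    articulation_features,
    detect_transitions,
    f0_contour,
    functionals,
    jitter_shimmer,
    phonation_feature_names,
    phonation_features,
    prosody_feature_names,
    prosody_features,
)
from parkfuse.features.prosody import fit_contour_poly
from parkfuse.synthetic import SAMPLE_RATE


class TestF0Contour:
    def test_sawtooth_pitch_recovered(self):
        period = SAMPLE_RATE // 200
        saw = ((np.arange(2 * SAMPLE_RATE) % period) / period) * 2 - 1
        contour = f0_contour(saw)
        voiced_f0 = contour.f0[contour.voiced]
        assert abs(np.median(voiced_f0) - 200.0) <= 2.0

    def test_white_noise_unvoiced(self):
        contour = f0_contour(np.random.default_rng(0).standard_normal(SAMPLE_RATE))
        assert contour.voiced.sum() == 0

    def test_silence_unvoiced(self):
        contour = f0_contour(np.zeros(SAMPLE_RATE))
        assert contour.voiced.sum() == 0

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            f0_contour(np.zeros(100))

    def test_voiced_f0_above_floor(self, vowel):
        contour = f0_contour(vowel)
        assert np.all(contour.f0[contour.voiced] >= 50.0)
        assert np.all(contour.f0[~contour.voiced] == 0.0)


class TestTransitions:
    def test_silence_then_vowel_has_one_onset_near_border(self, vowel):
        x = np.concatenate([np.zeros(SAMPLE_RATE), vowel[:SAMPLE_RATE]])
        ts = detect_transitions(f0_contour(x))
        assert len(ts.onsets) == 1
        center = sum(ts.onsets[0]) / 2
        assert abs(center - 1.0) <= 0.011  # within one frame hop

    def test_vowel_then_silence_has_one_offset(self, vowel):
        x = np.concatenate([vowel[:SAMPLE_RATE], np.zeros(SAMPLE_RATE)])
        ts = detect_transitions(f0_contour(x))
        assert len(ts.offsets) == 1
        assert len(ts.onsets) == 0

    def test_fully_voiced_recording_has_no_transitions(self, vowel):
        ts = detect_transitions(f0_contour(vowel))
        assert ts.onsets == [] and ts.offsets == []


class TestJitterShimmer:
    def test_periodic_train_zero_jitter(self):
        j, s = jitter_shimmer(np.full(20, 0.01), np.full(20, 0.5))
        assert j == 0.0 and s == 0.0

    def test_alternating_periods_formula(self):
        periods = np.tile([0.0099, 0.0101], 10)
        j, _ = jitter_shimmer(periods, np.ones(20))
        assert j == pytest.approx(2.0, rel=1e-9)

    def test_fewer_than_two_cycles_rejected(self):
        with pytest.raises(ValueError):
            jitter_shimmer([0.01], [0.5])

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        periods = 0.01 + 0.001 * rng.random(15)
        amps = 0.5 + 0.1 * rng.random(15)
        j0, s0 = jitter_shimmer(periods, amps)
        j1, s1 = jitter_shimmer(periods * scale, amps * scale)
        assert j1 == pytest.approx(j0, rel=1e-9)
        assert s1 == pytest.approx(s0, rel=1e-9)


class TestFunctionals:
    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.standard_normal(50)
            mean = sum(x) / len(x)
            var = sum((v - mean) ** 2 for v in x) / len(x)
            std = var**0.5
            skew = sum(((v - mean) / std) ** 3 for v in x) / len(x)
            kurt = sum(((v - mean) / std) ** 4 for v in x) / len(x) - 3.0
            got = functionals(x)
            assert np.allclose(got, [mean, std, skew, kurt], atol=1e-9)

    def test_degenerate_sequences(self):
        assert np.allclose(functionals(np.full(5, 2.0)), [2.0, 0.0, 0.0, 0.0])
        assert np.allclose(functionals(np.array([3.0])), [3.0, 0.0, 0.0, 0.0])


class TestPhonation:
    def test_dimension_contract(self, vowel):
        assert len(phonation_features(vowel)) == PHONATION_DIM == 28
        assert len(phonation_feature_names()) == 28

    def test_pure_tone_has_negligible_jitter(self, vowel):
        feats = phonation_features(vowel)
        names = phonation_feature_names()
        jitter_mean = feats[names.index("phonation_jitter_mean")]
        assert jitter_mean < 0.1

    def test_all_finite(self, vowel):
        assert np.isfinite(phonation_features(vowel)).all()

    def test_unvoiced_input_rejected(self):
        with pytest.raises(ValueError):
            phonation_features(np.random.default_rng(0).standard_normal(SAMPLE_RATE) * 0.1)


class TestArticulation:
    def test_dimension_contract(self, vowel_silence_vowel):
        feats = articulation_features(vowel_silence_vowel)
        assert len(feats) == ARTICULATION_DIM == 488
        assert len(articulation_feature_names()) == 488
        assert np.isfinite(feats).all()

    def test_single_transition_statistics_degenerate(self, vowel):
        """One onset and one offset: across-transition std/skew/kurt are 0."""
        x = np.concatenate([np.zeros(SAMPLE_RATE // 2), vowel[:SAMPLE_RATE], np.zeros(SAMPLE_RATE // 2)])
        feats = articulation_features(x)
        names = articulation_feature_names()
        for i, name in enumerate(names):
            if name.startswith("articulation_onset") and name.endswith(("_std", "_skew", "_kurt")):
                assert feats[i] == 0.0

    def test_no_transitions_rejected(self, vowel):
        with pytest.raises(ValueError):
            articulation_features(vowel)


class TestProsody:
    def test_dimension_contract(self, vowel_silence_vowel):
        feats = prosody_features(vowel_silence_vowel)
        assert len(feats) == PROSODY_DIM == 103
        assert len(prosody_feature_names()) == 103
        assert np.isfinite(feats).all()

    def test_constant_pitch_has_zero_f0_std(self, vowel):
        feats = prosody_features(vowel)
        names = prosody_feature_names()
        assert feats[names.index("prosody_f0_std")] < 0.5

    def test_degree5_polynomial_contour_recovered(self):
        coefs = np.array([120.0, 15.0, -8.0, 3.0, -1.5, 0.5])
        t = np.linspace(0.0, 1.0, 40)
        contour = sum(c * t**k for k, c in enumerate(coefs))
        got = fit_contour_poly(contour)
        assert np.allclose(got, coefs, atol=1e-6)

    def test_exactly_six_frames_interpolates(self):
        coefs = np.array([1.0, -2.0, 0.5, 4.0, -3.0, 2.0])
        t = np.linspace(0.0, 1.0, 6)
        contour = sum(c * t**k for k, c in enumerate(coefs))
        assert np.allclose(fit_contour_poly(contour), coefs, atol=1e-6)

    def test_unvoiced_input_rejected(self):
        with pytest.raises(ValueError):
            prosody_features(np.random.default_rng(1).standard_normal(SAMPLE_RATE) * 0.05)
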