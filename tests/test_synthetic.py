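"""Generator tests: determinism, null behaviour, cue construction."""

import dataclasses

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import cross_val_score

from parkfuse.synthetic import (
    SAMPLE_RATE,
    SubjectProfile,
    SynthConfig,
    generate_corpus,
    latent_aperture,
    load_corpus,
    opening_pixel_count,
    render_lip_frames,
    sample_profiles,
    save_corpus,
    synthesize_utterance,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SynthConfig(effect_size=-0.1)
    with pytest.raises(ValueError):
        SynthConfig(duration_s=0.5)
    with pytest.raises(ValueError):
        SynthConfig(coupling_mode="bogus")


def test_same_seed_gives_bit_identical_corpus():
    cfg = SynthConfig(n_subjects_per_class=2, utterances_per_subject=2, seed=5)
    a = generate_corpus(cfg)
    b = generate_corpus(cfg)
    for ra, rb in zip(a.records, b.records):
        assert np.array_equal(ra.waveform, rb.waveform)
        assert np.array_equal(ra.frames, rb.frames)


def test_null_effect_gives_identical_parameter_distributions():
    """At effect size zero the class-conditional parameter means agree."""
    cfg = SynthConfig(n_subjects_per_class=300, effect_size=0.0, seed=9)
    profiles = sample_profiles(cfg, np.random.default_rng(9))
    for field in ("modulation_depth", "jitter_level", "pause_rate", "base_f0"):
        hc = np.array([getattr(p, field) for p in profiles if p.label == "HC"])
        pd_ = np.array([getattr(p, field) for p in profiles if p.label == "PD"])
        pooled_sd = np.std(np.r_[hc, pd_])
        assert abs(hc.mean() - pd_.mean()) < 0.25 * pooled_sd


def test_strong_effect_separates_mean_aperture_excursion():
    """delta=2 shared mode: a linear classifier on per-subject mean mouth
    opening separates the classes with >= 90% cross-validated accuracy
    (Monte-Carlo over 10 seeds)."""
    accs = []
    for seed in range(10):
        cfg = SynthConfig(
            n_subjects_per_class=10,
            utterances_per_subject=2,
            effect_size=2.0,
            coupling_mode="shared",
            seed=200 + seed,
        )
        corpus = generate_corpus(cfg)
        by_subject: dict[str, list[float]] = {}
        label: dict[str, int] = {}
        for rec in corpus.records:
            counts = [opening_pixel_count(f) for f in rec.frames]
            by_subject.setdefault(rec.subject_id, []).extend(counts)
            label[rec.subject_id] = 1 if rec.label == "PD" else 0
        X = np.array([[np.mean(v), np.std(v)] for v in by_subject.values()])
        y = np.array([label[s] for s in by_subject])
        X = (X - X.mean(0)) / X.std(0)
        accs.append(cross_val_score(LogisticRegression(), X, y, cv=5).mean())
    assert np.mean(accs) >= 0.90


def test_jitter_free_pulse_train_has_equal_periods(hc_profile):
    """With zero jitter and no noise, consecutive glottal periods agree to
    within one sample (verified on the excitation peak times)."""
    profile = dataclasses.replace(hc_profile, jitter_level=0.0, pause_rate=0.0)
    rng = np.random.default_rng(0)
    wave, _ = synthesize_utterance(profile, 1.0, rng, snr_db=np.inf)
    # peak-pick the periodic excitation, avoiding the silent lead-in/out
    period = SAMPLE_RATE / profile.base_f0
    start, stop = int(0.15 * SAMPLE_RATE), int(0.85 * SAMPLE_RATE)
    peaks = []
    i = start + int(period)
    while i + period / 3 < stop:
        lo = int(i - period / 3)
        hi = int(i + period / 3)
        peaks.append(lo + int(np.argmax(wave[lo:hi])))
        i = peaks[-1] + int(round(period))
    periods = np.diff(peaks)
    assert len(periods) > 50
    # pulse placement is exact to 1 sample; peak-picking through the mouth
    # resonance adds up to 1 further sample of measurement quantization
    assert np.abs(np.diff(periods)).max() <= 2
    assert np.abs(periods - round(SAMPLE_RATE / profile.base_f0)).max() <= 2


def test_no_pauses_means_no_long_silences(hc_profile):
    profile = dataclasses.replace(hc_profile, pause_rate=0.0)
    wave, _ = synthesize_utterance(profile, 2.0, np.random.default_rng(1), snr_db=np.inf)
    thr = 0.02 * np.max(np.abs(wave))
    below = (np.abs(wave) < thr).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.r_[0, below, 0]))
    runs_ms = [(edges[i + 1] - edges[i]) / SAMPLE_RATE * 1e3 for i in range(0, len(edges), 2)]
    assert max(runs_ms, default=0.0) <= 100.0


def test_dominant_spectral_peak_tracks_f0(hc_profile):
    profile = dataclasses.replace(hc_profile, jitter_level=0.0, pause_rate=0.0)
    wave, _ = synthesize_utterance(profile, 2.0, np.random.default_rng(2), snr_db=np.inf)
    spec = np.abs(np.fft.rfft(wave * np.hanning(len(wave))))
    freqs = np.fft.rfftfreq(len(wave), 1.0 / SAMPLE_RATE)
    assert abs(freqs[spec.argmax()] - 150.0) <= 2.0


def test_zero_base_f0_rejected(hc_profile):
    profile = dataclasses.replace(hc_profile, base_f0=0.0)
    with pytest.raises(ValueError):
        synthesize_utterance(profile, 1.0, np.random.default_rng(0))


class TestLipFrames:
    def test_frame_shape_contract(self):
        frames = render_lip_frames(np.full(SAMPLE_RATE, 0.4), rng=np.random.default_rng(0))
        assert frames.shape == (7, 50, 100)
        assert frames.min() >= 0.0 and frames.max() <= 1.0

    def test_closed_mouth_frames_identical_without_noise(self):
        frames = render_lip_frames(np.zeros(SAMPLE_RATE), rng=None)
        for f in frames[1:]:
            assert np.array_equal(f, frames[0])

    def test_opening_pixel_count_monotone_in_aperture(self):
        n = 28 * SAMPLE_RATE // 7
        frames = render_lip_frames(np.linspace(0, 1, n), rng=None)
        counts = [opening_pixel_count(f) for f in frames]
        assert all(np.diff(counts) >= 0)
        assert counts[-1] > counts[0]

    def test_aperture_values_clamped(self):
        frames = render_lip_frames(np.linspace(-1, 2, SAMPLE_RATE), rng=None)
        assert frames.shape[0] == 7


def test_latent_aperture_range_and_band():
    ap = latent_aperture(2.0, np.random.default_rng(3))
    assert ap.min() >= 0.0 and ap.max() <= 1.0
    assert ap.min() == pytest.approx(0.0) and ap.max() == pytest.approx(1.0)


def test_corpus_roundtrip_through_wav_and_png(tmp_path):
    cfg = SynthConfig(n_subjects_per_class=1, utterances_per_subject=1, seed=3)
    corpus = generate_corpus(cfg)
    save_corpus(corpus, tmp_path)
    loaded = load_corpus(tmp_path)
    assert loaded.config == cfg
    orig, back = corpus.records[0], loaded.records[0]
    assert back.utterance_id == orig.utterance_id
    # PCM16 / 8-bit quantization bounds
    assert np.max(np.abs(orig.waveform - back.waveform)) < 1.0 / 32000
    assert np.max(np.abs(orig.frames - back.frames)) < 1.0 / 250


def test_metadata_matches_records(tiny_corpus):
    assert len(tiny_corpus.metadata) == len(tiny_corpus.records)
    assert set(tiny_corpus.metadata["label"]) == {"HC", "PD"}
    assert (tiny_corpus.metadata["n_frames"] == 7).all()
    assert (tiny_corpus.metadata["n_samples"] == SAMPLE_RATE).all()
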