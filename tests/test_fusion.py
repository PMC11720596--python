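"""Attention fusion tests: closed forms, oracles, invariances, and the
classical early/late/joint fusion baselines."""

import numpy as np
import pytest

from parkfuse.experiments import small_lip_config, small_speech_config
from parkfuse.fusion import (
    EarlyFusion,
    FusionModel,
    JointFusionModel,
    fuse_both,
    late_fuse,
    project_stream,
    scaled_dot_attention,
)
from parkfuse.nn import Tensor, softmax_cross_entropy


class TestScaledDotAttention:
    def test_single_key_returns_the_value_row(self):
        Q = np.random.default_rng(0).standard_normal((4, 3))
        K = np.array([[1.0, 2.0, 3.0]])
        V = np.array([[5.0, -1.0, 0.5]])
        out, w = scaled_dot_attention(Q, K, V)
        assert np.allclose(out, np.tile(V, (4, 1)))
        assert np.allclose(w, 1.0)

    def test_identical_keys_average_the_values(self):
        Q = np.random.default_rng(1).standard_normal((3, 2))
        K = np.tile([[0.3, -0.7]], (5, 1))
        V = np.random.default_rng(2).standard_normal((5, 4))
        out, w = scaled_dot_attention(Q, K, V)
        assert np.allclose(out, np.tile(V.mean(axis=0), (3, 1)))
        assert np.allclose(w, 0.2)

    def test_hand_computed_two_key_example(self):
        Q = np.array([[1.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        out, w = scaled_dot_attention(Q, K, V)
        s = 1.0 / np.sqrt(2.0)
        e = np.exp([s, 0.0])
        expected_w = e / e.sum()
        assert np.allclose(w[0], expected_w)
        assert np.allclose(out[0], expected_w @ V)

    def test_rows_sum_to_one_and_lie_in_unit_interval(self):
        rng = np.random.default_rng(3)
        _, w = scaled_dot_attention(rng.standard_normal((6, 8)) * 10, rng.standard_normal((9, 8)), rng.standard_normal((9, 2)))
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((w >= 0) & (w <= 1))

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            Q, K, V = rng.standard_normal((5, 4)), rng.standard_normal((5, 4)), rng.standard_normal((5, 4))
            out, w = scaled_dot_attention(Q, K, V)
            for i in range(5):
                scores = np.array([Q[i] @ K[j] / 2.0 for j in range(5)])
                e = np.exp(scores - scores.max())
                probs = e / e.sum()
                assert np.abs(w[i] - probs).max() < 1e-9
                assert np.abs(out[i] - probs @ V).max() < 1e-9

    def test_joint_key_value_permutation_invariance(self):
        rng = np.random.default_rng(5)
        Q, K, V = rng.standard_normal((3, 4)), rng.standard_normal((6, 4)), rng.standard_normal((6, 4))
        out, _ = scaled_dot_attention(Q, K, V)
        perm = rng.permutation(6)
        out_p, _ = scaled_dot_attention(Q, K[perm], V[perm])
        assert np.allclose(out, out_p)

    def test_query_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        Q, K, V = rng.standard_normal((5, 4)), rng.standard_normal((6, 4)), rng.standard_normal((6, 4))
        out, _ = scaled_dot_attention(Q, K, V)
        perm = rng.permutation(5)
        out_p, _ = scaled_dot_attention(Q[perm], K, V)
        assert np.allclose(out_p, out[perm])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((4, 5)), np.zeros((4, 5)))
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((4, 3)), np.zeros((5, 3)))


class TestProjectStream:
    def test_speech_onto_lips_has_lip_timeline(self):
        rng = np.random.default_rng(7)
        speech = rng.standard_normal((145, 64))
        lips = rng.standard_normal((7, 64))
        fused = project_stream(source=speech, target=lips, direction="speech_to_lip")
        assert fused.sequence.shape == (7, 64)
        assert fused.pooled.shape == (64,)

    def test_lips_onto_speech_has_speech_timeline(self):
        rng = np.random.default_rng(8)
        fused = project_stream(
            source=rng.standard_normal((7, 64)), target=rng.standard_normal((145, 64))
        )
        assert fused.sequence.shape == (145, 64)

    def test_self_projection_reduces_to_self_attention(self):
        rng = np.random.default_rng(9)
        seq = rng.standard_normal((6, 8))
        fused = project_stream(source=seq, target=seq)
        expected, _ = scaled_dot_attention(seq, seq, seq)
        assert np.allclose(fused.sequence, expected)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            project_stream(np.zeros((5, 8)), np.zeros((3, 4)))

    def test_both_directions_concatenate_to_128(self):
        rng = np.random.default_rng(10)
        fused = fuse_both(rng.standard_normal((145, 64)), rng.standard_normal((7, 64)))
        assert fused.pooled.shape == (128,)
        assert fused.direction == "both"


class TestEarlyFusion:
    def test_training_folds_are_zscored_and_concatenated(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal((20, 619)) * 3 + 1
        b = rng.standard_normal((20, 255)) * 0.1 - 4
        ef = EarlyFusion()
        fused = ef.fit_transform(a, b)
        assert fused.shape == (20, 874)
        assert np.abs(fused.mean(axis=0)).max() < 1e-9
        assert np.abs(fused.std(axis=0) - 1).max() < 1e-9

    def test_sample_count_mismatch_rejected(self):
        ef = EarlyFusion().fit(np.zeros((4, 3)), np.zeros((4, 2)))
        with pytest.raises(ValueError):
            ef.transform(np.zeros((4, 3)), np.zeros((5, 2)))

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            EarlyFusion().transform(np.zeros((3, 2)))


class TestLateFusion:
    def test_mean_rule_arithmetic(self):
        decision, score = late_fuse([0.1, 0.9], [0.4, 0.6], method="mean")
        assert np.allclose(score, [0.25, 0.75])
        assert decision == 1

    def test_identical_posteriors_agree_with_either_model(self):
        for method in ("mean", "max", "product"):
            decision, _ = late_fuse([0.8, 0.2], [0.8, 0.2], method=method)
            assert decision == 0

    def test_exact_tie_breaks_to_pd(self):
        decision, _ = late_fuse([0.5, 0.5], [0.5, 0.5], method="mean")
        assert decision == 1

    def test_unnormalized_posteriors_rejected(self):
        with pytest.raises(ValueError):
            late_fuse([0.5, 0.6], [0.5, 0.5], method="mean")

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            late_fuse([0.5, 0.5], [0.5, 0.5], method="median")


@pytest.fixture(scope="module")
def tiny_batch():
    rng = np.random.default_rng(12)
    audio = rng.standard_normal((2, 48_000)).astype(np.float32)
    frames = rng.random((2, 7, 25, 50)).astype(np.float32)
    return audio, frames


class TestFusionModels:
    def test_gradients_reach_both_encoders(self, tiny_batch):
        audio, frames = tiny_batch
        model = FusionModel(small_speech_config(), small_lip_config(), direction="both", seed=0)
        # non-degenerate head so logit gradients propagate into the pool
        model.classifier.weight.data[...] = 0.05 * np.random.default_rng(1).standard_normal(
            model.classifier.weight.shape
        ).astype(np.float32)
        logits = model.forward_logits(audio, frames, training=False)
        loss = softmax_cross_entropy(logits, np.array([0, 1]))
        loss.backward()
        speech_norm = sum(float(np.abs(p.grad).sum()) for p in model.speech.parameters() if p.grad is not None)
        lip_norm = sum(float(np.abs(p.grad).sum()) for p in model.lip.parameters() if p.grad is not None)
        assert speech_norm > 0
        assert lip_norm > 0

    def test_single_direction_head_width(self, tiny_batch):
        audio, frames = tiny_batch
        for direction in ("speech_to_lip", "lip_to_speech"):
            model = FusionModel(small_speech_config(), small_lip_config(), direction=direction, seed=0)
            logits = model.forward_logits(audio, frames)
            assert logits.shape == (2, 2)
            d = model.speech.config.embedding_dim
            assert model.classifier.weight.shape == (d, 2)

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            FusionModel(small_speech_config(), small_lip_config(), direction="sideways")

    def test_joint_model_reduces_to_linear_head_on_mean_embeddings(self, tiny_batch):
        """With frozen encoders, joint fusion is exactly a linear model on
        the concatenated time-averaged embeddings."""
        audio, frames = tiny_batch
        model = JointFusionModel(small_speech_config(), small_lip_config(), seed=0)
        logits = model.forward_logits(audio, frames, training=False).data
        speech_seq, _ = model.speech.forward(audio, training=False)
        lip_seq = model.lip.forward_sequence(frames, training=False)
        pooled = np.concatenate([speech_seq.data.mean(axis=1), lip_seq.data.mean(axis=1)], axis=1)
        expected = pooled @ model.classifier.weight.data + model.classifier.bias.data
        assert np.abs(logits - expected).max() < 1e-5

    def test_joint_training_decreases_loss_on_separable_batch(self):
        rng = np.random.default_rng(13)
        n = 8
        audio = np.stack(
            [(0.9 if i % 2 else 0.1) * rng.standard_normal(48_000) for i in range(n)]
        ).astype(np.float32)
        frames = np.stack(
            [np.full((7, 25, 50), 0.8 if i % 2 else 0.2) for i in range(n)]
        ).astype(np.float32)
        y = np.arange(n) % 2
        model = JointFusionModel(small_speech_config(), small_lip_config(), seed=0)
        from parkfuse.nn import Adam

        optim = Adam(model.parameters(), lr=1e-3, weight_decay=0.0)
        losses = []
        for _ in range(8):
            optim.zero_grad()
            loss = softmax_cross_entropy(model.forward_logits(audio, frames, training=True), y)
            loss.backward()
            optim.step()
            losses.append(float(loss.data))
        assert losses[-1] < losses[0]

    def test_warm_start_copies_unimodal_weights(self):
        from parkfuse.lip_encoder import LipEncoder
        from parkfuse.speech_encoder import SpeechEncoder

        speech = SpeechEncoder(small_speech_config(), seed=1)
        lip = LipEncoder(small_lip_config(), seed=2)
        model = FusionModel(small_speech_config(), small_lip_config(), direction="both", seed=0)
        model.init_from(speech, lip)
        assert np.array_equal(model.speech.conv1.weight.data, speech.conv1.weight.data)
        assert np.array_equal(model.lip.stem.weight.data, lip.stem.weight.data)
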