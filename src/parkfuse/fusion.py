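"""Fusion of the speech and lip streams.

The synchronous strategy projects one modality's temporal sequence onto
the other's timeline with single-head scaled dot-product attention,

    Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V,

then averages over time for a static representation.  The naming
convention here: in an "X-to-Y projection", X is the *source* whose
information is projected onto target Y's time axis — Q derives from Y,
K and V from X, and the output has Y's length (7 steps for
speech-to-lip, 145 for lip-to-speech).  "Both" concatenates the two
pooled projections into a 128-value vector for the classifier head.

Classical baselines: early fusion (z-scored feature concatenation), late
fusion of posteriors (max / mean / product rules) and joint fusion (a
shared head over concatenated intermediate embeddings, trained end to
end so the loss reaches both encoders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .lip_encoder import LipEncoder, LipEncoderConfig
from .speech_encoder import SpeechEncoder, SpeechEncoderConfig

__all__ = [
    "AttentionConfig",
    "FusedRepresentation",
    "scaled_dot_attention",
    "project_stream",
    "fuse_both",
    "EarlyFusion",
    "late_fuse",
    "FusionModel",
    "JointFusionModel",
    "DIRECTIONS",
]

DIRECTIONS = ("speech_to_lip", "lip_to_speech", "both")


@dataclass(frozen=True)
class AttentionConfig:
    d_model: int = 64
    use_projections: bool = True  # learned bias-free linear maps for Q, K, V


@dataclass
class FusedRepresentation:
    sequence: np.ndarray  # (T_target, d) — empty for direction "both"
    pooled: np.ndarray  # temporal mean (d,) or concatenation (2d,)
    direction: str
    attention: np.ndarray | None = field(default=None, repr=False)


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-head attention on plain arrays; returns (output, weights).

    Weights are the row-stochastic matrix softmax(Q K^T / sqrt(d_k)).
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.ndim != 2 or K.ndim != 2 or V.ndim != 2:
        raise ValueError("Q, K, V must be 2-D (time x dim)")
    if Q.shape[1] != K.shape[1]:
        raise ValueError(f"query dim {Q.shape[1]} != key dim {K.shape[1]}")
    if K.shape[0] != V.shape[0]:
        raise ValueError(f"{K.shape[0]} keys but {V.shape[0]} values")
    scores = Q @ K.T / np.sqrt(K.shape[1])
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=1, keepdims=True)
    return weights @ V, weights


def project_stream(
    source: np.ndarray,
    target: np.ndarray,
    direction: str = "",
    weights_qkv: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> FusedRepresentation:
    """Project ``source``'s information onto ``target``'s time axis.

    Q comes from the target, K and V from the source; optional learned
    projection matrices (Wq, Wk, Wv) are applied first.  The output
    sequence has the target's length; ``pooled`` is its temporal mean.
    """
    source = np.asarray(source, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if source.shape[1] != target.shape[1]:
        raise ValueError("source and target embedding widths differ")
    q, k, v = target, source, source
    if weights_qkv is not None:
        wq, wk, wv = weights_qkv
        q, k, v = q @ wq, k @ wk, v @ wv
    out, attn = scaled_dot_attention(q, k, v)
    return FusedRepresentation(
        sequence=out, pooled=out.mean(axis=0), direction=direction, attention=attn
    )


def fuse_both(speech_seq: np.ndarray, lip_seq: np.ndarray, config: AttentionConfig | None = None) -> FusedRepresentation:
    """Concatenate the pooled speech-to-lip and lip-to-speech projections."""
    s2l = project_stream(source=speech_seq, target=lip_seq, direction="speech_to_lip")
    l2s = project_stream(source=lip_seq, target=speech_seq, direction="lip_to_speech")
    return FusedRepresentation(
        sequence=np.zeros((0, speech_seq.shape[1])),
        pooled=np.concatenate([s2l.pooled, l2s.pooled]),
        direction="both",
    )


class EarlyFusion:
    """Concatenation of feature blocks after per-feature z-scoring.

    The scaler statistics are fitted on training-fold data only.
    """

    def __init__(self):
        self.means: list[np.ndarray] | None = None
        self.stds: list[np.ndarray] | None = None

    def fit(self, *train_blocks: np.ndarray) -> "EarlyFusion":
        self.means = [np.asarray(b).mean(axis=0) for b in train_blocks]
        self.stds = [np.maximum(np.asarray(b).std(axis=0), 1e-12) for b in train_blocks]
        return self

    def transform(self, *blocks: np.ndarray) -> np.ndarray:
        if self.means is None:
            raise RuntimeError("EarlyFusion must be fitted on training folds first")
        if len({np.asarray(b).shape[0] for b in blocks}) != 1:
            raise ValueError("feature blocks disagree on the number of samples")
        parts = [
            (np.asarray(b) - m) / s for b, m, s in zip(blocks, self.means, self.stds)
        ]
        return np.concatenate(parts, axis=1)

    def fit_transform(self, *blocks: np.ndarray) -> np.ndarray:
        return self.fit(*blocks).transform(*blocks)


def late_fuse(
    posteriors_a: np.ndarray, posteriors_b: np.ndarray, method: str = "mean"
) -> tuple[int, np.ndarray]:
    """Combine two class posteriors [p_hc, p_pd]; returns (decision, score).

    Decision 1 = PD.  ``mean`` thresholds the averaged p_pd at 0.5; ``max``
    and ``product`` take the per-class maximum / product and argmax.  Exact
    ties break toward PD (the clinically conservative call).
    """
    pa = np.asarray(posteriors_a, dtype=np.float64)
    pb = np.asarray(posteriors_b, dtype=np.float64)
    for p in (pa, pb):
        if p.shape != (2,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("posteriors must be normalized pairs")
    if method == "mean":
        score = (pa + pb) / 2.0
        return (1 if score[1] >= 0.5 else 0), score
    if method == "max":
        score = np.maximum(pa, pb)
    elif method == "product":
        score = pa * pb
    else:
        raise ValueError(f"unknown late-fusion method {method!r}")
    return (1 if score[1] >= score[0] else 0), score


class _AttentionHead(nn.Module):
    """Learned bias-free Q/K/V projections for one direction."""

    def __init__(self, d_model: int, rng: np.random.Generator, use_projections: bool):
        self.use_projections = use_projections
        if use_projections:
            # near-uniform attention at initialization: small query/key
            # maps keep the scores close to zero, and the identity value
            # map passes the source embeddings through unchanged, so the
            # block starts as a temporal mean and learns to specialize
            scale = 0.1 / np.sqrt(d_model)
            self.wq = self._mat(d_model, scale, rng)
            self.wk = self._mat(d_model, scale, rng)
            self.wv = self._mat(d_model, scale, rng, identity=True)

    @staticmethod
    def _mat(d: int, scale: float, rng, identity: bool = False) -> Tensor:
        w = rng.normal(0.0, scale, size=(d, d))
        if identity:
            w += np.eye(d)
        t = Tensor(w.astype(np.float32))
        t.requires_grad = True
        return t

    def __call__(self, target_seq: Tensor, source_seq: Tensor) -> Tensor:
        q, k, v = target_seq, source_seq, source_seq
        if self.use_projections:
            q, k, v = q @ self.wq, k @ self.wk, v @ self.wv
        d_k = q.shape[-1]
        scores = (q @ k.transpose(0, 2, 1)) / float(np.sqrt(d_k))
        weights = nn.softmax(scores, axis=-1)
        return weights @ v


class FusionModel(nn.Module):
    """Synchronous attention fusion of both encoders, trained end to end."""

    def __init__(
        self,
        speech_config: SpeechEncoderConfig | None = None,
        lip_config: LipEncoderConfig | None = None,
        direction: str = "both",
        attention: AttentionConfig | None = None,
        seed: int = 0,
    ):
        if direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        self.direction = direction
        self.speech = SpeechEncoder(speech_config, seed=seed)
        self.lip = LipEncoder(lip_config, seed=seed + 1)
        d_model = self.speech.config.embedding_dim
        if d_model != self.lip.config.embedding_dim:
            raise ValueError("speech and lip embedding widths must match for attention")
        self.attention_config = attention or AttentionConfig(d_model=d_model)
        rng = np.random.default_rng(seed + 2)
        use_proj = self.attention_config.use_projections
        self.head_s2l = _AttentionHead(d_model, rng, use_proj)
        self.head_l2s = _AttentionHead(d_model, rng, use_proj)
        head_in = 2 * d_model if direction == "both" else d_model
        self.classifier = nn.Linear(head_in, 2, rng)
        # zero-started head: early fine-tuning gradients cannot scramble
        # warm-started encoders through random logit weights
        self.classifier.weight.data[...] = 0.0
        self._modality_rng = np.random.default_rng(seed + 9)

    def init_from(self, speech: SpeechEncoder, lip: LipEncoder) -> "FusionModel":
        """Warm-start the encoders from trained unimodal models."""
        self.speech.load_state_dict(speech.state_dict())
        self.lip.load_state_dict(lip.state_dict())
        return self

    def slow_parameters(self) -> list[Tensor]:
        """Encoder parameters, fine-tuned at a reduced learning rate."""
        return self.speech.parameters() + self.lip.parameters()

    @staticmethod
    def augment_batch(inputs: tuple[np.ndarray, ...], rng: np.random.Generator) -> tuple:
        """Sync-preserving augmentation: audio gain plus photometric frame
        jitter (no time shifts, which would break cross-modal alignment)."""
        audio, frames = inputs
        n = audio.shape[0]
        gain = rng.uniform(0.6, 1.4, size=(n, 1)).astype(audio.dtype)
        (aug_frames,) = LipEncoder.augment_batch((frames,), rng)
        return (audio * gain, aug_frames)

    def head_parameters(self) -> list[Tensor]:
        """Attention projections and classifier weights."""
        params = self.classifier.parameters()
        for head in (self.head_s2l, self.head_l2s):
            params += head.parameters()
        return params

    def _pooled(self, audio, frames, training: bool) -> Tensor:
        speech_seq, _ = self.speech.forward(audio, training)
        lip_seq = self.lip.forward_sequence(frames, training)
        return self._pool_sequences(speech_seq, lip_seq, training)

    def _pool_sequences(self, speech_seq, lip_seq, training: bool) -> Tensor:
        speech_seq = speech_seq if isinstance(speech_seq, Tensor) else Tensor(speech_seq)
        lip_seq = lip_seq if isinstance(lip_seq, Tensor) else Tensor(lip_seq)
        parts = []
        if self.direction in ("speech_to_lip", "both"):
            fused = self.head_s2l(lip_seq, speech_seq)  # Q from lips
            parts.append(fused.mean(axis=1))
        if self.direction in ("lip_to_speech", "both"):
            fused = self.head_l2s(speech_seq, lip_seq)  # Q from speech
            parts.append(fused.mean(axis=1))
        if len(parts) == 1:
            return parts[0]
        if training:
            # modality dropout: randomly silence one projection per sample
            # so each half of the fused vector stays independently
            # predictive instead of co-adapting
            n = parts[0].shape[0]
            draw = self._modality_rng.random(n)
            keep_a = Tensor((draw >= 0.25).astype(np.float32)[:, None])
            keep_b = Tensor((draw < 0.75).astype(np.float32)[:, None])
            parts = [parts[0] * keep_a, parts[1] * keep_b]
        return nn.concat(parts, axis=1)

    def forward_logits(self, audio, frames, training: bool = False) -> Tensor:
        return self.classifier(self._pooled(audio, frames, training))

    def forward_logits_from_sequences(self, speech_seq, lip_seq, training: bool = False) -> Tensor:
        """Attention + head on precomputed encoder sequences."""
        return self.classifier(self._pool_sequences(speech_seq, lip_seq, training))

    def fused_representation(self, audio: np.ndarray, frames: np.ndarray) -> np.ndarray:
        """Pooled fusion vector(s) for a batch, in inference mode."""
        return self._pooled(audio, frames, training=False).data


class JointFusionModel(nn.Module):
    """Joint (intermediate) fusion: shared linear head over the
    concatenated time-averaged embeddings of both encoders; the single
    loss backpropagates into both feature extractors."""

    def __init__(
        self,
        speech_config: SpeechEncoderConfig | None = None,
        lip_config: LipEncoderConfig | None = None,
        seed: int = 0,
    ):
        self.speech = SpeechEncoder(speech_config, seed=seed)
        self.lip = LipEncoder(lip_config, seed=seed + 1)
        rng = np.random.default_rng(seed + 2)
        head_in = self.speech.config.embedding_dim + self.lip.config.embedding_dim
        self.classifier = nn.Linear(head_in, 2, rng)

    def init_from(self, speech: SpeechEncoder, lip: LipEncoder) -> "JointFusionModel":
        """Warm-start the encoders from trained unimodal models."""
        self.speech.load_state_dict(speech.state_dict())
        self.lip.load_state_dict(lip.state_dict())
        return self

    def slow_parameters(self) -> list[Tensor]:
        """Encoder parameters, fine-tuned at a reduced learning rate."""
        return self.speech.parameters() + self.lip.parameters()

    augment_batch = staticmethod(FusionModel.augment_batch)

    def head_parameters(self) -> list[Tensor]:
        return self.classifier.parameters()

    def forward_logits(self, audio, frames, training: bool = False) -> Tensor:
        speech_seq, _ = self.speech.forward(audio, training)
        lip_seq = self.lip.forward_sequence(frames, training)
        return self.forward_logits_from_sequences(speech_seq, lip_seq, training)

    def forward_logits_from_sequences(self, speech_seq, lip_seq, training: bool = False) -> Tensor:
        speech_seq = speech_seq if isinstance(speech_seq, Tensor) else Tensor(speech_seq)
        lip_seq = lip_seq if isinstance(lip_seq, Tensor) else Tensor(lip_seq)
        pooled = nn.concat([speech_seq.mean(axis=1), lip_seq.mean(axis=1)], axis=1)
        return self.classifier(pooled)
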