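"""End-to-end speech encoder: strided 1-D convolutions on the raw 48 kHz
waveform, temporal max pooling, a two-layer bidirectional LSTM, and a
three-layer fully connected classifier head.

With the canonical geometry a 1 s segment (48 000 samples) passes through
stage lengths 3961 -> 1980 -> 291 -> 145; the recurrent stage emits a
145 x 64 sequence embedding (32 hidden units per direction, concatenated)
which is both the fusion interface and, flattened to 9280 values, the
input of the 9280 -> 1024 -> 256 -> 2 classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .synthetic import SAMPLE_RATE

__all__ = ["SpeechEncoderConfig", "SpeechEncoder", "speech_forward", "posterior_from_logits"]


@dataclass(frozen=True)
class SpeechEncoderConfig:
    input_samples: int = SAMPLE_RATE
    conv1_channels: int = 16
    conv1_kernel: int = 480
    conv1_stride: int = 12
    conv2_channels: int = 32
    conv2_kernel: int = 240
    conv2_stride: int = 6
    lstm_hidden: int = 32  # per direction; embedding width is twice this
    lstm_layers: int = 2
    fc_hidden: tuple[int, int] = (1024, 256)
    dropout: float = 0.3

    @property
    def embedding_dim(self) -> int:
        return 2 * self.lstm_hidden

    def stage_lengths(self) -> dict[str, int]:
        """Temporal length after each stage for the configured input."""
        l1 = (self.input_samples - self.conv1_kernel) // self.conv1_stride + 1
        p1 = l1 // 2
        l2 = (p1 - self.conv2_kernel) // self.conv2_stride + 1
        p2 = l2 // 2
        return {"conv1": l1, "pool1": p1, "conv2": l2, "pool2": p2}

    @property
    def n_steps(self) -> int:
        return self.stage_lengths()["pool2"]

    @property
    def flatten_dim(self) -> int:
        return self.n_steps * self.embedding_dim


def posterior_from_logits(logits: np.ndarray) -> np.ndarray:
    """Softmax posteriors, rows ordered [p_hc, p_pd]."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SpeechEncoder(nn.Module):
    """Raw-waveform classifier emitting a per-step sequence embedding."""

    def __init__(self, config: SpeechEncoderConfig | None = None, seed: int = 0):
        self.config = config or SpeechEncoderConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.conv1 = nn.Conv1d(1, cfg.conv1_channels, cfg.conv1_kernel, cfg.conv1_stride, rng)
        self.bn1 = nn.BatchNorm(cfg.conv1_channels)
        self.conv2 = nn.Conv1d(
            cfg.conv1_channels, cfg.conv2_channels, cfg.conv2_kernel, cfg.conv2_stride, rng
        )
        self.bn2 = nn.BatchNorm(cfg.conv2_channels)
        self.lstm = nn.LSTM(cfg.conv2_channels, cfg.lstm_hidden, cfg.lstm_layers, rng)
        self.fc1 = nn.Linear(cfg.flatten_dim, cfg.fc_hidden[0], rng)
        self.fc2 = nn.Linear(cfg.fc_hidden[0], cfg.fc_hidden[1], rng)
        self.fc3 = nn.Linear(cfg.fc_hidden[1], 2, rng)

    def forward(self, audio, training: bool = False) -> tuple[Tensor, Tensor]:
        """Return (sequence embedding (N, T, D), logits (N, 2))."""
        x = audio if isinstance(audio, Tensor) else Tensor(np.asarray(audio, dtype=np.float32))
        if x.ndim == 1:
            x = x.reshape(1, -1)
        n, length = x.shape
        if length != self.config.input_samples:
            raise ValueError(
                f"expected {self.config.input_samples} samples per segment, got {length}"
            )
        h = x.reshape(n, 1, length)
        h = nn.relu(self.bn1(self.conv1(h), training))
        h = nn.maxpool1d_pairs(h)
        h = nn.relu(self.bn2(self.conv2(h), training))
        h = nn.maxpool1d_pairs(h)
        seq = self.lstm(h.transpose(0, 2, 1))  # (N, T, 2*hidden)
        flat = seq.reshape(n, self.config.flatten_dim)
        f = nn.relu(self.fc1(flat))
        f = nn.dropout(f, self.config.dropout, self._dropout_rng, training)
        f = nn.relu(self.fc2(f))
        f = nn.dropout(f, self.config.dropout, self._dropout_rng, training)
        return seq, self.fc3(f)

    def forward_logits(self, audio, training: bool = False) -> Tensor:
        return self.forward(audio, training)[1]

    @staticmethod
    def augment_batch(inputs: tuple[np.ndarray, ...], rng: np.random.Generator) -> tuple:
        """Training-time augmentation: random gain, circular time shift and
        random resampling (pitch shift).

        All three preserve the pathology cues — jitter is a *relative*
        period perturbation and survives resampling, pauses and envelope
        dynamics survive shifts and gain — while breaking speaker-identity
        shortcuts such as absolute level, phrase timing and habitual pitch.
        """
        (audio,) = inputs
        n, length = audio.shape
        gain = rng.uniform(0.6, 1.4, size=(n, 1)).astype(audio.dtype)
        out = np.empty_like(audio)
        base = np.arange(length, dtype=np.float64)
        for i in range(n):
            rate = rng.uniform(0.8, 1.25)
            src = np.mod(base * rate + rng.integers(0, length), length)
            out[i] = np.interp(src, base, audio[i].astype(np.float64)).astype(audio.dtype)
        return (out * gain,)


def speech_forward(model: SpeechEncoder, audio: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inference on one 1 s segment: (T x D embedding, [p_hc, p_pd])."""
    seq, logits = model.forward(np.asarray(audio, dtype=np.float32)[None, :], training=False)
    return seq.data[0], posterior_from_logits(logits.data)[0]
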