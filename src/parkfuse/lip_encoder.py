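"""Residual lip-frame encoder: a 3x3 stem convolution, three stages of
residual blocks (16/32/64 maps, stride-2 entry into stages 2 and 3),
global average pooling to a 64-value per-frame embedding, and a linear
classifier head.

Each residual block computes H(x) = F(x) + shortcut(x) with
F = conv-norm-ReLU-conv-norm and ReLU after the addition; the shortcut is
the identity except when the block changes width or resolution, where a
1x1 projection convolution is used.  With a 50x100 input the stage grids
are 50x100 -> 25x50 -> 13x25 (ceil division) and the final pooled
embedding has 64 values per frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .speech_encoder import posterior_from_logits
from .synthetic import FPS, FRAME_SHAPE

__all__ = ["LipEncoderConfig", "ResidualBlock", "LipEncoder", "lip_forward", "lip_forward_sequence"]


@dataclass(frozen=True)
class LipEncoderConfig:
    input_shape: tuple[int, int] = FRAME_SHAPE  # (height, width)
    stem_channels: int = 16
    stage_widths: tuple[int, ...] = (16, 32, 64)
    blocks_per_stage: int = 2
    dropout: float = 0.3

    @property
    def embedding_dim(self) -> int:
        return self.stage_widths[-1]

    def stage_grids(self) -> list[tuple[int, int]]:
        """Spatial grid after each stage (ceil division on downsampling)."""
        h, w = self.input_shape
        grids = []
        for i in range(len(self.stage_widths)):
            if i > 0:
                h, w = (h + 1) // 2, (w + 1) // 2
            grids.append((h, w))
        return grids


class ResidualBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.bn1 = nn.BatchNorm(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.bn2 = nn.BatchNorm(c_out)
        self.projection = None
        if stride != 1 or c_in != c_out:
            self.projection = nn.Conv2d(c_in, c_out, 1, stride, 0, rng)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        f = nn.relu(self.bn1(self.conv1(x), training))
        f = self.bn2(self.conv2(f), training)
        shortcut = self.projection(x) if self.projection is not None else x
        return nn.relu(f + shortcut)


class LipEncoder(nn.Module):
    """Per-frame residual CNN with a 64-value pooled embedding."""

    def __init__(self, config: LipEncoderConfig | None = None, seed: int = 0):
        self.config = config or LipEncoderConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.stem = nn.Conv2d(1, cfg.stem_channels, 3, 1, 1, rng)
        self.stem_bn = nn.BatchNorm(cfg.stem_channels)
        self.blocks: list[ResidualBlock] = []
        c_in = cfg.stem_channels
        for i, width in enumerate(cfg.stage_widths):
            for b in range(cfg.blocks_per_stage):
                stride = 2 if (i > 0 and b == 0) else 1
                self.blocks.append(ResidualBlock(c_in, width, stride, rng))
                c_in = width
        self.head = nn.Linear(cfg.embedding_dim, 2, rng)

    def forward_frames(self, frames, training: bool = False) -> tuple[Tensor, Tensor]:
        """(N, H, W) or (N, 1, H, W) frames -> (embeddings (N, D), logits)."""
        x = frames if isinstance(frames, Tensor) else Tensor(np.asarray(frames, dtype=np.float32))
        if x.ndim == 3:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        if x.shape[2:] != tuple(self.config.input_shape):
            raise ValueError(
                f"expected {self.config.input_shape} frames, got {tuple(x.shape[2:])}"
            )
        h = nn.relu(self.stem_bn(self.stem(x), training))
        for block in self.blocks:
            h = block(h, training)
        emb = h.mean(axis=(2, 3))  # global average pool over the spatial grid
        emb_d = nn.dropout(emb, self.config.dropout, self._dropout_rng, training)
        return emb, self.head(emb_d)

    def forward_logits(self, frames, training: bool = False) -> Tensor:
        return self.forward_frames(frames, training)[1]

    @staticmethod
    def augment_batch(inputs: tuple[np.ndarray, ...], rng: np.random.Generator) -> tuple:
        """Training-time augmentation: brightness/contrast jitter and
        horizontal flips — photometric nuisances under which mouth-opening
        geometry is invariant."""
        (frames,) = inputs
        n = frames.shape[0]
        extra = (1,) * (frames.ndim - 1)
        gain = rng.uniform(0.85, 1.15, size=(n, *extra)).astype(frames.dtype)
        offset = rng.uniform(-0.08, 0.08, size=(n, *extra)).astype(frames.dtype)
        out = np.clip(frames * gain + offset, 0.0, 1.0)
        flip = rng.random(n) < 0.5
        out[flip] = out[flip, ..., ::-1]
        return (out,)

    def forward_sequence(self, frames, training: bool = False) -> Tensor:
        """(N, 7, H, W) frame sequences -> (N, 7, D) embeddings, order kept."""
        x = frames if isinstance(frames, Tensor) else Tensor(np.asarray(frames, dtype=np.float32))
        n, t = x.shape[0], x.shape[1]
        if t != FPS:
            raise ValueError(f"expected {FPS} frames per segment, got {t}")
        flat = x.reshape(n * t, *x.shape[2:])
        emb, _ = self.forward_frames(flat, training)
        return emb.reshape(n, t, self.config.embedding_dim)


def lip_forward(model: LipEncoder, frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inference on one lip image: (64-value embedding, [p_hc, p_pd])."""
    emb, logits = model.forward_frames(np.asarray(frame, dtype=np.float32)[None], training=False)
    return emb.data[0], posterior_from_logits(logits.data)[0]


def lip_forward_sequence(model: LipEncoder, frames: np.ndarray) -> np.ndarray:
    """Inference on the 7 frames of one segment -> 7 x 64 embedding."""
    seq = model.forward_sequence(np.asarray(frames, dtype=np.float32)[None], training=False)
    return seq.data[0]
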