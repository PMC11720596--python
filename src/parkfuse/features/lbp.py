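"""Local binary pattern texture descriptors for lip images.

Each interior pixel is compared with 8 neighbors on a radius-1 circle,
sampled clockwise starting from the top neighbor; off-grid positions
(the four diagonals) are bilinearly interpolated.  A neighbor at least as
bright as the center sets its bit (ties count as >=), the first sampled
neighbor being the most significant bit, giving a code in [0, 255].  Codes
over all interior pixels are binned into 255 equal-width bins spanning
[0, 256) and normalized to sum 1 — the 255-dimensional texture histogram.
Comparisons are grayscale-shift and positive-scale invariant.
"""

from __future__ import annotations

import numpy as np

LBP_DIM = 255
# (dy, dx) offsets, clockwise from the top neighbor; y grows downward
_SQ2 = np.sqrt(2.0) / 2.0
_OFFSETS = [
    (-1.0, 0.0),
    (-_SQ2, _SQ2),
    (0.0, 1.0),
    (_SQ2, _SQ2),
    (1.0, 0.0),
    (_SQ2, -_SQ2),
    (0.0, -1.0),
    (-_SQ2, -_SQ2),
]

__all__ = ["LBP_DIM", "lbp_code", "lbp_image", "lbp_histogram", "lbp_features"]


def lbp_code(center: float, neighbors) -> int:
    """Decimal LBP code from 8 neighbor intensities sampled clockwise.

    Bit b is set when ``neighbors[b] >= center``; the first neighbor is the
    most significant bit.
    """
    neighbors = np.asarray(neighbors, dtype=np.float64)
    if neighbors.shape != (8,):
        raise ValueError("exactly 8 neighbors required")
    bits = neighbors >= center
    return int(sum(int(b) << (7 - i) for i, b in enumerate(bits)))


def _interp_neighbor(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Neighbor intensity at offset (dy, dx) for every interior pixel."""
    h, w = img.shape
    ys = np.arange(1, h - 1)[:, None] + dy
    xs = np.arange(1, w - 1)[None, :] + dx
    # clip the base corner so the far corner stays inside the image; the
    # fractional weights computed afterwards keep the sample position exact
    y0 = np.minimum(np.floor(ys).astype(int), h - 2)
    x0 = np.minimum(np.floor(xs).astype(int), w - 2)
    fy = ys - y0
    fx = xs - x0
    return (
        img[y0, x0] * (1 - fy) * (1 - fx)
        + img[y0, x0 + 1] * (1 - fy) * fx
        + img[y0 + 1, x0] * fy * (1 - fx)
        + img[y0 + 1, x0 + 1] * fy * fx
    )


def lbp_image(image: np.ndarray) -> np.ndarray:
    """LBP code of every interior pixel of a 2-D intensity grid."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be 2-D with at least a 3x3 interior")
    center = img[1:-1, 1:-1]
    # interpolation of an exactly-constant patch can undershoot the center
    # by a few ulps; the tie rule (>=) must still fire
    eps = 1e-9 * (np.max(np.abs(img)) + 1.0)
    codes = np.zeros(center.shape, dtype=np.int64)
    for bit, (dy, dx) in enumerate(_OFFSETS):
        nb = _interp_neighbor(img, dy, dx)
        codes |= (nb >= center - eps).astype(np.int64) << (7 - bit)
    return codes


def lbp_histogram(image: np.ndarray) -> np.ndarray:
    """Normalized 255-bin histogram of LBP codes over the image interior."""
    codes = lbp_image(image)
    hist, _ = np.histogram(codes, bins=LBP_DIM, range=(0.0, 256.0))
    return hist / hist.sum()


def lbp_features(frames: np.ndarray) -> np.ndarray:
    """Per-utterance LBP descriptor: per-frame histograms, averaged."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    return np.mean([lbp_histogram(f) for f in frames], axis=0)


def lbp_feature_names() -> list[str]:
    return [f"lbp_bin{i:03d}" for i in range(LBP_DIM)]
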