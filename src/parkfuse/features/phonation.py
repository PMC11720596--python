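"""Phonation features: stability of vocal-fold vibration.

Seven per-frame descriptor sequences over the voiced frames — first and
second F0 differences, jitter, shimmer, five-point amplitude perturbation
quotient (APQ), five-point pitch perturbation quotient (PPQ), and log
energy — each summarized by the four statistical functionals, giving the
28-dimensional phonation vector.
"""

from __future__ import annotations

import numpy as np

from ..synthetic import SAMPLE_RATE
from .functionals import FUNCTIONAL_NAMES, functionals
from .voicing import F0Contour, f0_contour, frame_signal

PHONATION_DESCRIPTORS = ("df0", "ddf0", "jitter", "shimmer", "apq", "ppq", "log_energy")
PHONATION_DIM = len(PHONATION_DESCRIPTORS) * len(FUNCTIONAL_NAMES)  # 28

__all__ = [
    "PHONATION_DIM",
    "PHONATION_DESCRIPTORS",
    "jitter_shimmer",
    "phonation_features",
    "phonation_feature_names",
]


def jitter_shimmer(periods: np.ndarray, amplitudes: np.ndarray) -> tuple[float, float]:
    """Cycle-to-cycle perturbation percentages.

    jitter = mean |consecutive period difference| / mean period x 100;
    shimmer is the analogous quantity on peak amplitudes.
    """
    periods = np.asarray(periods, dtype=np.float64)
    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    if periods.size < 2 or amplitudes.size < 2:
        raise ValueError("jitter/shimmer need at least 2 cycles")
    jitter = float(np.mean(np.abs(np.diff(periods))) / np.mean(periods) * 100.0)
    shimmer = float(np.mean(np.abs(np.diff(amplitudes))) / np.mean(amplitudes) * 100.0)
    return jitter, shimmer


def _perturbation_quotient(values: np.ndarray, k: int = 5) -> np.ndarray:
    """|value - k-point moving average| / overall mean, in percent."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < k:
        return np.zeros(0)
    half = k // 2
    kernel = np.ones(k) / k
    smooth = np.convolve(values, kernel, mode="valid")
    center = values[half : len(values) - half]
    return np.abs(center - smooth) / values.mean() * 100.0


def _descriptor_sequences(x: np.ndarray, contour: F0Contour, rate: int) -> dict[str, np.ndarray]:
    voiced_idx = np.flatnonzero(contour.voiced)
    f0v = contour.f0[voiced_idx]
    periods = 1.0 / f0v
    frames = frame_signal(x, rate)
    amps = np.max(np.abs(frames[voiced_idx]), axis=1)
    energies = np.sum(frames[voiced_idx] ** 2, axis=1)
    jitter_seq = np.abs(np.diff(periods)) / periods.mean() * 100.0
    shimmer_seq = np.abs(np.diff(amps)) / amps.mean() * 100.0 if amps.mean() > 0 else np.zeros(0)
    return {
        "df0": np.diff(f0v),
        "ddf0": np.diff(f0v, n=2) if f0v.size > 2 else np.zeros(0),
        "jitter": jitter_seq,
        "shimmer": shimmer_seq,
        "apq": _perturbation_quotient(amps),
        "ppq": _perturbation_quotient(periods),
        "log_energy": 10.0 * np.log10(energies + 1e-12),
    }


def phonation_features(samples, rate: int = SAMPLE_RATE) -> np.ndarray:
    """28-dimensional phonation vector; raises if < 2 voiced frames."""
    x = np.asarray(getattr(samples, "samples", samples), dtype=np.float64)
    contour = f0_contour(x, rate)
    if int(contour.voiced.sum()) < 2:
        raise ValueError("phonation features need at least 2 voiced frames")
    seqs = _descriptor_sequences(x, contour, rate)
    return np.concatenate([functionals(seqs[name]) for name in PHONATION_DESCRIPTORS])


def phonation_feature_names() -> list[str]:
    return [f"phonation_{d}_{f}" for d in PHONATION_DESCRIPTORS for f in FUNCTIONAL_NAMES]
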