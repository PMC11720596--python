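"""Prosody features: intonation, loudness dynamics and rhythm (103 values).

The enumeration implemented here is normative for this package:

====================================================================  =====
block                                                                 count
====================================================================  =====
F0 statistics over voiced frames (mean, std, min, max, skew, kurt)        6
global F0 slope (linear fit over voiced frames, Hz/s)                     1
degree-5 polynomial pitch-contour coefficients per voiced segment,
  6 coefficients x 4 functionals across segments                         24
log-energy statistics over voiced frames                                  6
global log-energy slope                                                   1
degree-5 polynomial energy-contour coefficients per voiced segment       24
per-voiced-segment shape descriptors (duration, F0 excursion,
  F0 slope, energy excursion, energy slope, F0 mean) x 4 functionals     24
rhythm: voiced rate, pause rate, voiced fraction; voiced-duration
  mean/std/skew/kurt/max/min; pause-duration mean/std/skew/kurt/
  max/min; pairwise variability index of voiced and pause durations      17
====================================================================  =====

Pitch and energy contours within a voiced segment are fitted by a degree-5
polynomial in normalized time (least squares; exact interpolation when the
segment has exactly 6 frames).  Segments with fewer frames use the highest
degree the data supports and pad the remaining coefficients with zero.
A pause is an unvoiced stretch of at least 100 ms.
"""

from __future__ import annotations

import numpy as np

from ..synthetic import SAMPLE_RATE
from .functionals import FUNCTIONAL_NAMES, functionals
from .voicing import f0_contour, frame_signal, voiced_runs

POLY_DEGREE = 5
MIN_PAUSE_S = 0.100
SEGMENT_DESCRIPTORS = ("duration", "f0_excursion", "f0_slope", "energy_excursion", "energy_slope", "f0_mean")
RHYTHM_NAMES = (
    "voiced_rate",
    "pause_rate",
    "voiced_fraction",
    "voiced_dur_mean",
    "voiced_dur_std",
    "voiced_dur_skew",
    "voiced_dur_kurt",
    "voiced_dur_max",
    "voiced_dur_min",
    "pause_dur_mean",
    "pause_dur_std",
    "pause_dur_skew",
    "pause_dur_kurt",
    "pause_dur_max",
    "pause_dur_min",
    "pvi_voiced",
    "pvi_pause",
)
PROSODY_DIM = 6 + 1 + 24 + 6 + 1 + 24 + 24 + len(RHYTHM_NAMES)  # 103

__all__ = ["PROSODY_DIM", "prosody_features", "prosody_feature_names", "fit_contour_poly"]


def _stats6(x: np.ndarray) -> np.ndarray:
    mean, std, skew, kurt = functionals(x)
    return np.array([mean, std, float(x.min()), float(x.max()), skew, kurt])


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    if len(y) < 2:
        return 0.0
    return float(np.polyfit(t, y, 1)[0])


def fit_contour_poly(values: np.ndarray, degree: int = POLY_DEGREE) -> np.ndarray:
    """Polynomial coefficients (ascending order, padded to ``degree+1``)
    fitted to a contour on normalized time [0, 1]."""
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    coefs = np.zeros(degree + 1)
    if n == 1:
        coefs[0] = values[0]
        return coefs
    t = np.linspace(0.0, 1.0, n)
    d = min(degree, n - 1)
    fit = np.polyfit(t, values, d)[::-1]  # ascending
    coefs[: d + 1] = fit
    return coefs


def _pvi(durations: np.ndarray) -> float:
    """Pairwise variability index (percent)."""
    if len(durations) < 2:
        return 0.0
    d = np.asarray(durations, dtype=np.float64)
    pair = np.abs(np.diff(d)) / ((d[:-1] + d[1:]) / 2.0)
    return float(pair.mean() * 100.0)


def prosody_features(samples, rate: int = SAMPLE_RATE) -> np.ndarray:
    """103-dimensional prosody vector; raises without voiced segments."""
    x = np.asarray(getattr(samples, "samples", samples), dtype=np.float64)
    contour = f0_contour(x, rate)
    runs = voiced_runs(contour)
    if not runs:
        raise ValueError("prosody features need at least one voiced segment")
    frames = frame_signal(x, rate)
    log_energy = 10.0 * np.log10(np.sum(frames**2, axis=1) + 1e-12)
    times = contour.frame_times()
    voiced_idx = np.flatnonzero(contour.voiced)
    f0v = contour.f0[voiced_idx]
    ev = log_energy[voiced_idx]
    tv = times[voiced_idx]

    f0_polys, en_polys, shapes = [], [], []
    for start, stop in runs:
        seg_f0 = contour.f0[start:stop]
        seg_en = log_energy[start:stop]
        seg_t = times[start:stop]
        f0_polys.append(fit_contour_poly(seg_f0))
        en_polys.append(fit_contour_poly(seg_en))
        shapes.append(
            [
                seg_t[-1] - seg_t[0] + contour.frame_hop,
                float(seg_f0.max() - seg_f0.min()),
                _slope(seg_t, seg_f0),
                float(seg_en.max() - seg_en.min()),
                _slope(seg_t, seg_en),
                float(seg_f0.mean()),
            ]
        )
    f0_polys = np.stack(f0_polys)
    en_polys = np.stack(en_polys)
    shapes = np.stack(shapes)

    hop = contour.frame_hop
    total_s = contour.duration_s
    voiced_durs = shapes[:, 0]
    # pauses: unvoiced runs of at least MIN_PAUSE_S
    u = (~contour.voiced).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.r_[0, u, 0]))
    pause_durs = np.array(
        [
            (edges[i + 1] - edges[i]) * hop
            for i in range(0, len(edges), 2)
            if (edges[i + 1] - edges[i]) * hop >= MIN_PAUSE_S
        ]
    )

    rhythm = np.array(
        [
            len(runs) / total_s,
            len(pause_durs) / total_s,
            float(voiced_durs.sum() / total_s),
            *functionals(voiced_durs),
            float(voiced_durs.max()),
            float(voiced_durs.min()),
            *(functionals(pause_durs) if pause_durs.size else np.zeros(4)),
            float(pause_durs.max()) if pause_durs.size else 0.0,
            float(pause_durs.min()) if pause_durs.size else 0.0,
            _pvi(voiced_durs),
            _pvi(pause_durs),
        ]
    )

    return np.concatenate(
        [
            _stats6(f0v),
            [_slope(tv, f0v)],
            np.concatenate([functionals(f0_polys[:, j]) for j in range(POLY_DEGREE + 1)]),
            _stats6(ev),
            [_slope(tv, ev)],
            np.concatenate([functionals(en_polys[:, j]) for j in range(POLY_DEGREE + 1)]),
            np.concatenate([functionals(shapes[:, j]) for j in range(len(SEGMENT_DESCRIPTORS))]),
            rhythm,
        ]
    )


def prosody_feature_names() -> list[str]:
    names = [f"prosody_f0_{s}" for s in ("mean", "std", "min", "max", "skew", "kurt")]
    names.append("prosody_f0_slope")
    names += [
        f"prosody_f0_poly_c{j}_{f}" for j in range(POLY_DEGREE + 1) for f in FUNCTIONAL_NAMES
    ]
    names += [f"prosody_energy_{s}" for s in ("mean", "std", "min", "max", "skew", "kurt")]
    names.append("prosody_energy_slope")
    names += [
        f"prosody_energy_poly_c{j}_{f}" for j in range(POLY_DEGREE + 1) for f in FUNCTIONAL_NAMES
    ]
    names += [f"prosody_seg_{d}_{f}" for d in SEGMENT_DESCRIPTORS for f in FUNCTIONAL_NAMES]
    names += [f"prosody_{r}" for r in RHYTHM_NAMES]
    return names
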