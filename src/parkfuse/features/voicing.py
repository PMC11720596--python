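"""Fundamental-frequency contour and voiced/unvoiced transition detection.

F0 is estimated per 40 ms frame with a 10 ms hop by normalized
autocorrelation restricted to the 50-500 Hz lag range; a frame is voiced
when its periodicity strength exceeds a threshold and its energy is above
a silence gate.  Onset (unvoiced-to-voiced) and offset (voiced-to-unvoiced)
transitions carry an 80 ms analysis window, 40 ms on each side of the
voicing border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..synthetic import SAMPLE_RATE

FRAME_LEN_S = 0.040
FRAME_HOP_S = 0.010
F0_MIN = 50.0
F0_MAX = 500.0
VOICING_THRESHOLD = 0.45
TRANSITION_HALF_S = 0.040

__all__ = [
    "F0Contour",
    "TransitionSet",
    "f0_contour",
    "detect_transitions",
    "voiced_runs",
    "frame_signal",
]


@dataclass
class F0Contour:
    f0: np.ndarray  # Hz per frame, 0 where unvoiced
    voiced: np.ndarray  # bool per frame
    frame_hop: float = FRAME_HOP_S
    frame_len: float = FRAME_LEN_S
    duration_s: float = 0.0

    def frame_times(self) -> np.ndarray:
        """Center time of each analysis frame."""
        return np.arange(len(self.f0)) * self.frame_hop + self.frame_len / 2


@dataclass
class TransitionSet:
    onsets: list[tuple[float, float]] = field(default_factory=list)
    offsets: list[tuple[float, float]] = field(default_factory=list)


def frame_signal(x: np.ndarray, rate: int = SAMPLE_RATE) -> np.ndarray:
    """Slice a waveform into the canonical 40 ms / 10 ms frames."""
    frame_n = int(round(FRAME_LEN_S * rate))
    hop_n = int(round(FRAME_HOP_S * rate))
    if len(x) < frame_n:
        raise ValueError(f"signal shorter than one {FRAME_LEN_S * 1e3:.0f} ms frame")
    n_frames = 1 + (len(x) - frame_n) // hop_n
    view = np.lib.stride_tricks.sliding_window_view(x, frame_n)[::hop_n][:n_frames]
    return view


def f0_contour(samples, rate: int = SAMPLE_RATE, voicing_threshold: float = VOICING_THRESHOLD) -> F0Contour:
    """Autocorrelation F0 per frame; 0 where unvoiced."""
    x = np.asarray(getattr(samples, "samples", samples), dtype=np.float64)
    frames = frame_signal(x, rate)
    frame_n = frames.shape[1]
    lag_min = int(np.floor(rate / F0_MAX))
    lag_max = int(np.ceil(rate / F0_MIN))
    centered = frames - frames.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(centered**2, axis=1))
    gate = 0.01 * (rms.max() if rms.max() > 0 else 1.0)
    nfft = int(2 ** np.ceil(np.log2(2 * frame_n)))
    spec = np.fft.rfft(centered, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, : lag_max + 2]
    f0 = np.zeros(len(frames))
    voiced = np.zeros(len(frames), dtype=bool)
    for i in range(len(frames)):
        if rms[i] <= gate or ac[i, 0] <= 0:
            continue
        r = ac[i] / ac[i, 0]
        seg = r[lag_min : lag_max + 1]
        k = int(np.argmax(seg)) + lag_min
        strength = r[k]
        if strength < voicing_threshold:
            continue
        # parabolic refinement of the lag peak
        if 0 < k < lag_max + 1:
            y0, y1, y2 = r[k - 1], r[k], r[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            k = k + float(np.clip(delta, -0.5, 0.5))
        k = float(np.clip(k, rate / F0_MAX, rate / F0_MIN))
        f0[i] = rate / k
        voiced[i] = True
    return F0Contour(f0=f0, voiced=voiced, duration_s=len(x) / rate)


def voiced_runs(contour: F0Contour) -> list[tuple[int, int]]:
    """Contiguous voiced frame runs as (start, stop) index pairs (stop excl.)."""
    v = np.asarray(contour.voiced, dtype=np.int8)
    edges = np.flatnonzero(np.diff(np.r_[0, v, 0]))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def detect_transitions(contour: F0Contour) -> TransitionSet:
    """Voicing-border intervals: 40 ms on each side of every flag flip."""
    times = contour.frame_times()
    v = contour.voiced
    duration = contour.duration_s or (times[-1] + contour.frame_len / 2 if len(times) else 0.0)
    out = TransitionSet()
    for i in range(1, len(v)):
        if v[i] == v[i - 1]:
            continue
        border = 0.5 * (times[i - 1] + times[i])
        lo = max(border - TRANSITION_HALF_S, 0.0)
        hi = min(border + TRANSITION_HALF_S, duration)
        if v[i]:
            out.onsets.append((lo, hi))
        else:
            out.offsets.append((lo, hi))
    return out
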