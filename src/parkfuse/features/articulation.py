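"""Articulation features: spectral dynamics around voicing transitions.

For every onset (unvoiced-to-voiced) and offset (voiced-to-unvoiced)
border, an 80 ms window is described by 22 Bark-band log energies plus 12
MFCCs and their first and second derivatives (58 descriptors).  Onset and
offset descriptor sets are summarized separately by the four functionals
(2 x 58 x 4 = 464).  First and second formants over the voiced frames,
with their first and second differences, contribute 6 further descriptor
sequences (24 values), for a 488-dimensional vector.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct
from scipy.linalg import solve_toeplitz
from scipy.signal import decimate, get_window

from ..synthetic import SAMPLE_RATE
from .functionals import FUNCTIONAL_NAMES, functionals
from .voicing import f0_contour, detect_transitions, voiced_runs

N_BARK = 22
N_MFCC = 12
N_MELS = 26
TRANSITION_DESCRIPTORS = N_BARK + 3 * N_MFCC  # 58 per transition
FORMANT_DESCRIPTORS = ("f1", "f2", "df1", "df2", "ddf1", "ddf2")
ARTICULATION_DIM = 2 * TRANSITION_DESCRIPTORS * 4 + len(FORMANT_DESCRIPTORS) * 4  # 488

__all__ = [
    "ARTICULATION_DIM",
    "articulation_features",
    "articulation_feature_names",
    "mfcc_matrix",
    "bark_band_energies",
]


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_fft: int, rate: int, n_mels: int = N_MELS, fmax: float = 8000.0) -> np.ndarray:
    edges = _mel_to_hz(np.linspace(_hz_to_mel(0.0), _hz_to_mel(fmax), n_mels + 2))
    freqs = np.fft.rfftfreq(n_fft, 1.0 / rate)
    bank = np.zeros((n_mels, len(freqs)))
    for i in range(n_mels):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / (mid - lo)
        down = (hi - freqs) / (hi - mid)
        bank[i] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def mfcc_matrix(x: np.ndarray, rate: int, n_mfcc: int = N_MFCC, frame_s: float = 0.020, hop_s: float = 0.005) -> np.ndarray:
    """MFCCs (c1..c12) per short frame of a signal window."""
    frame_n = int(round(frame_s * rate))
    hop_n = int(round(hop_s * rate))
    if len(x) < frame_n:
        x = np.pad(x, (0, frame_n - len(x)))
    frames = np.lib.stride_tricks.sliding_window_view(x, frame_n)[::hop_n]
    window = get_window("hann", frame_n)
    spec = np.abs(np.fft.rfft(frames * window, axis=1)) ** 2
    bank = _mel_filterbank(frame_n, rate)
    mel_energy = np.log(spec @ bank.T + 1e-12)
    cepstra = dct(mel_energy, type=2, norm="ortho", axis=1)
    return cepstra[:, 1 : n_mfcc + 1]


def _bark_scale(f: np.ndarray) -> np.ndarray:
    return 13.0 * np.arctan(0.00076 * f) + 3.5 * np.arctan((f / 7500.0) ** 2)


def bark_band_energies(x: np.ndarray, rate: int, n_bands: int = N_BARK) -> np.ndarray:
    """Log energy in the first ``n_bands`` Bark bands of a signal window."""
    window = get_window("hann", len(x))
    psd = np.abs(np.fft.rfft(x * window)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1.0 / rate)
    z = _bark_scale(freqs)
    out = np.empty(n_bands)
    for b in range(n_bands):
        mask = (z >= b) & (z < b + 1)
        out[b] = np.log(psd[mask].sum() + 1e-12)
    return out


def _deltas(seq: np.ndarray) -> np.ndarray:
    """First differences along frames, same length (gradient)."""
    if len(seq) < 2:
        return np.zeros_like(seq)
    return np.gradient(seq, axis=0)


def _transition_descriptors(x: np.ndarray, rate: int, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    seg = x[int(lo * rate) : int(hi * rate)]
    if len(seg) < int(0.005 * rate):
        seg = np.pad(seg, (0, int(0.005 * rate) - len(seg)))
    bark = bark_band_energies(seg, rate)
    mf = mfcc_matrix(seg, rate)
    dmf = _deltas(mf)
    ddmf = _deltas(dmf)
    return np.concatenate([bark, mf.mean(axis=0), dmf.mean(axis=0), ddmf.mean(axis=0)])


def _lpc(x: np.ndarray, order: int) -> np.ndarray | None:
    x = x - x.mean()
    if np.max(np.abs(x)) < 1e-10:
        return None
    r = np.correlate(x, x, mode="full")[len(x) - 1 : len(x) + order]
    if r[0] <= 0:
        return None
    r = r / r[0]
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        return None
    return a


def _frame_formants(frame: np.ndarray, rate: int, order: int = 16) -> tuple[float, float] | None:
    a = _lpc(frame * get_window("hamming", len(frame)), order)
    if a is None:
        return None
    roots = np.roots(np.r_[1.0, -a])
    roots = roots[np.imag(roots) > 1e-6]
    freqs = np.angle(roots) * rate / (2 * np.pi)
    bws = -rate / np.pi * np.log(np.abs(roots))
    cand = sorted(f for f, b in zip(freqs, bws) if 90.0 < f < 3500.0 and b < 700.0)
    f1 = next((f for f in cand if 200.0 <= f <= 1000.0), None)
    if f1 is None:
        return None
    f2 = next((f for f in cand if f > f1 + 200.0 and 800.0 <= f <= 3000.0), None)
    if f2 is None:
        return None
    return float(f1), float(f2)


def _formant_sequences(x: np.ndarray, rate: int, contour) -> dict[str, np.ndarray]:
    # formants are estimated on a 16 kHz version (LPC is better conditioned
    # when the band of interest dominates the spectrum)
    x16 = decimate(x, rate // 16_000, zero_phase=True) if rate > 16_000 else x
    r16 = 16_000 if rate > 16_000 else rate
    frame_n = int(0.040 * r16)
    hop_n = int(0.010 * r16)
    f1s, f2s = [], []
    for start, stop in voiced_runs(contour):
        for i in range(start, stop):
            lo = i * hop_n
            frame = x16[lo : lo + frame_n]
            if len(frame) < frame_n:
                continue
            res = _frame_formants(frame, r16)
            if res is not None:
                f1s.append(res[0])
                f2s.append(res[1])
    f1 = np.asarray(f1s)
    f2 = np.asarray(f2s)
    return {
        "f1": f1,
        "f2": f2,
        "df1": np.diff(f1) if f1.size > 1 else np.zeros(0),
        "df2": np.diff(f2) if f2.size > 1 else np.zeros(0),
        "ddf1": np.diff(f1, n=2) if f1.size > 2 else np.zeros(0),
        "ddf2": np.diff(f2, n=2) if f2.size > 2 else np.zeros(0),
    }


def articulation_features(samples, rate: int = SAMPLE_RATE) -> np.ndarray:
    """488-dimensional articulation vector; raises without transitions."""
    x = np.asarray(getattr(samples, "samples", samples), dtype=np.float64)
    contour = f0_contour(x, rate)
    transitions = detect_transitions(contour)
    if not transitions.onsets or not transitions.offsets:
        raise ValueError("articulation features need at least one onset and one offset transition")
    parts = []
    for intervals in (transitions.onsets, transitions.offsets):
        desc = np.stack([_transition_descriptors(x, rate, iv) for iv in intervals])
        parts.append(np.concatenate([functionals(desc[:, j]) for j in range(desc.shape[1])]))
    formants = _formant_sequences(x, rate, contour)
    parts.append(np.concatenate([functionals(formants[name]) for name in FORMANT_DESCRIPTORS]))
    return np.concatenate(parts)


def articulation_feature_names() -> list[str]:
    names = []
    base = (
        [f"bark{b:02d}" for b in range(N_BARK)]
        + [f"mfcc{c:02d}" for c in range(1, N_MFCC + 1)]
        + [f"dmfcc{c:02d}" for c in range(1, N_MFCC + 1)]
        + [f"ddmfcc{c:02d}" for c in range(1, N_MFCC + 1)]
    )
    for kind in ("onset", "offset"):
        for b in base:
            for f in FUNCTIONAL_NAMES:
                names.append(f"articulation_{kind}_{b}_{f}")
    for d in FORMANT_DESCRIPTORS:
        for f in FUNCTIONAL_NAMES:
            names.append(f"articulation_{d}_{f}")
    return names
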