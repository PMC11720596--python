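"""Standardization of raw audio/video and time-aligned 1 s bimodal segments.

Audio is resampled to 48 kHz, DC-removed and peak-normalized.  Video is
brought to 7 FPS by nearest-timestamp frame selection, roll-aligned using
the inter-eye line, and reduced to 50x100 grayscale lip crops.  The atomic
unit handed to the models is a :class:`BimodalSegment`: exactly 48 000 audio
samples paired with the 7 lip frames covering the same wall-clock second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly
from skimage.transform import resize, rotate

from .synthetic import FPS, FRAME_SHAPE, SAMPLE_RATE, Corpus

__all__ = [
    "AudioTrack",
    "LipVideo",
    "BimodalSegment",
    "standardize_audio",
    "resample_video",
    "align_roll",
    "extract_lip_roi",
    "segment_pairs",
    "segments_from_corpus",
]


@dataclass
class AudioTrack:
    samples: np.ndarray
    rate: int = SAMPLE_RATE
    is_silent: bool = False


@dataclass
class LipVideo:
    frames: np.ndarray  # (n, 50, 100) in [0, 1]
    fps: int = FPS
    dropped_frame_indices: list[int] = field(default_factory=list)


@dataclass
class BimodalSegment:
    audio: np.ndarray  # exactly SAMPLE_RATE samples
    frames: np.ndarray  # exactly FPS frames, each 50x100
    subject_id: str
    label: str


def standardize_audio(waveform: np.ndarray, native_rate: int) -> AudioTrack:
    """Resample to 48 kHz, remove DC offset, normalize peak amplitude to 1.

    An all-zero (digitally silent) input is returned unchanged with
    ``is_silent`` set, skipping the normalization.
    """
    if native_rate <= 0:
        raise ValueError("native_rate must be positive")
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.size == 0:
        raise ValueError("empty waveform")
    if native_rate != SAMPLE_RATE:
        ratio = Fraction(SAMPLE_RATE, int(native_rate))
        waveform = resample_poly(waveform, ratio.numerator, ratio.denominator)
    waveform = waveform - waveform.mean()
    peak = float(np.max(np.abs(waveform)))
    if peak < 1e-12:
        return AudioTrack(samples=np.zeros_like(waveform), is_silent=True)
    return AudioTrack(samples=waveform / peak, is_silent=False)


def resample_video(frames: np.ndarray, source_fps: float) -> LipVideo:
    """Downsample to 7 FPS by nearest-timestamp frame selection."""
    if source_fps < FPS:
        raise ValueError(f"source fps {source_fps} below target {FPS}; upsampling unsupported")
    frames = np.asarray(frames)
    n_src = len(frames)
    duration = n_src / source_fps
    n_out = int(np.floor(duration * FPS))
    idx = np.clip(np.round(np.arange(n_out) * source_fps / FPS).astype(int), 0, n_src - 1)
    return LipVideo(frames=frames[idx], fps=FPS)


def align_roll(
    frame: np.ndarray,
    left_eye_center: tuple[float, float],
    right_eye_center: tuple[float, float],
) -> np.ndarray:
    """Rotate the frame about the eye midpoint so the inter-eye line is level.

    Eye centers are (x, y) pixel coordinates, origin top-left, y downward.
    The rotation angle is ``-atan2(dy, dx)``; interpolation is bilinear.
    """
    (x1, y1), (x2, y2) = left_eye_center, right_eye_center
    dx, dy = x2 - x1, y2 - y1
    if abs(dx) < 1e-12 and abs(dy) < 1e-12:
        raise ValueError("eye centers coincide")
    angle_deg = -np.degrees(np.arctan2(dy, dx))
    center = ((x1 + x2) / 2.0, (y1 + y2) / 2.0)
    return rotate(frame, -angle_deg, center=center, order=1, preserve_range=True, mode="constant")


def extract_lip_roi(
    frame: np.ndarray,
    lip_landmarks: np.ndarray | None,
    margin: float = 0.10,
) -> np.ndarray | None:
    """Crop the lip bounding box (with margin), grayscale, resize to 50x100.

    Returns ``None`` as the dropped-frame signal when landmarks are missing
    or the box has zero area, mirroring the discard rule for frames where
    the face could not be located.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 3:  # RGB -> luminance
        frame = frame @ np.array([0.299, 0.587, 0.114])
    if lip_landmarks is None or len(lip_landmarks) == 0:
        return None
    pts = np.asarray(lip_landmarks, dtype=np.float64)
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    if x1 - x0 <= 0 or y1 - y0 <= 0:
        return None
    mx, my = margin * (x1 - x0), margin * (y1 - y0)
    r0 = max(int(np.floor(y0 - my)), 0)
    r1 = min(int(np.ceil(y1 + my)) + 1, frame.shape[0])
    c0 = max(int(np.floor(x0 - mx)), 0)
    c1 = min(int(np.ceil(x1 + mx)) + 1, frame.shape[1])
    if r1 - r0 < 1 or c1 - c0 < 1:
        return None
    crop = frame[r0:r1, c0:c1]
    out = resize(crop, FRAME_SHAPE, order=1, preserve_range=True, anti_aliasing=True)
    lo, hi = float(out.min()), float(out.max())
    if hi > 1.0 or lo < 0.0:  # rescale e.g. 8-bit input into [0, 1]
        out = (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
    return np.clip(out, 0.0, 1.0)


def segment_pairs(track: AudioTrack, video: LipVideo, subject_id: str = "", label: str = "") -> list[BimodalSegment]:
    """Cut a paired recording into non-overlapping 1 s bimodal segments.

    Segment i takes audio samples [48000*i, 48000*(i+1)) and frames
    [7*i, 7*i+7).  The trailing partial second is discarded, as is any
    segment where more than half of the frames were dropped upstream.
    """
    if track.rate != SAMPLE_RATE or video.fps != FPS:
        raise ValueError("track/video must be standardized first")
    n_sec = min(len(track.samples) // SAMPLE_RATE, len(video.frames) // FPS)
    dropped = set(video.dropped_frame_indices)
    segments = []
    for i in range(n_sec):
        frame_ids = range(FPS * i, FPS * i + FPS)
        if sum(1 for f in frame_ids if f in dropped) > FPS // 2:
            continue
        segments.append(
            BimodalSegment(
                audio=track.samples[SAMPLE_RATE * i : SAMPLE_RATE * (i + 1)],
                frames=video.frames[FPS * i : FPS * i + FPS],
                subject_id=subject_id,
                label=label,
            )
        )
    return segments


def segments_from_corpus(corpus: Corpus) -> list[BimodalSegment]:
    """Standardize every synthetic utterance and cut it into 1 s segments."""
    segments: list[BimodalSegment] = []
    for rec in corpus.records:
        track = standardize_audio(rec.waveform, SAMPLE_RATE)
        video = LipVideo(frames=rec.frames, fps=FPS)
        segments.extend(segment_pairs(track, video, rec.subject_id, rec.label))
    return segments
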