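"""Synthetic paired audio + lip-video corpus with controllable class structure.

The real clinical recordings behind this problem (read speech plus frontal
face video of Parkinson's patients and healthy controls) are private, so the
package ships a generator that emulates the two hypokinetic phenomena the
models are meant to pick up:

* **Hypokinetic dysarthria** in the audio stream — a glottal pulse train at a
  subject-specific fundamental frequency, with cycle-to-cycle period
  perturbation (jitter), amplitude modulation that follows mouth opening, a
  mouth-tracking resonance, and silent pauses.
* **Reduced mouth excursion** in the video stream — 50x100 grayscale lip
  frames at 7 FPS whose dark inner opening tracks a latent aperture
  trajectory (a sum of three 1-4 Hz sinusoids, mimicking syllabic rates).

A single ``effect_size`` knob (delta) scales every class difference: at
delta = 0 the PD and HC parameter distributions coincide exactly; the
"PD-like" direction is reduced modulation depth, raised jitter and raised
pause rate, shifting linearly with delta.

``coupling_mode`` controls where the class information lives:

* ``shared`` — one aperture trajectory drives both the lip opening and the
  audio envelope, so the excursion cue is visible in both streams.
* ``complementary`` — the excursion cue is routed to video only (audio uses
  a fixed, class-neutral envelope) while jitter and pauses are audible only,
  so each stream alone carries strictly less information than both together.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.io import wavfile
from scipy.ndimage import gaussian_filter
from scipy.signal import butter, lfilter, sosfilt

SAMPLE_RATE = 48_000
FPS = 7
FRAME_SHAPE = (50, 100)  # rows (height) x columns (width)

# healthy-control parameter distributions (means, SDs) and the PD-like shift
# applied per unit of effect size; SDs are between-subject variability
_HC_MEANS = {"modulation_depth": 0.75, "jitter_level": 0.010, "pause_rate": 0.30, "base_f0": 140.0}
_HC_SDS = {"modulation_depth": 0.05, "jitter_level": 0.003, "pause_rate": 0.08, "base_f0": 25.0}
_PD_SHIFT = {"modulation_depth": -0.10, "jitter_level": +0.03, "pause_rate": +0.35, "base_f0": 0.0}

# audio envelope in complementary mode uses this fixed, class-neutral depth
_NEUTRAL_MODULATION = _HC_MEANS["modulation_depth"]

__all__ = [
    "SAMPLE_RATE",
    "FPS",
    "FRAME_SHAPE",
    "SynthConfig",
    "SubjectProfile",
    "UtteranceRecord",
    "Corpus",
    "sample_profiles",
    "latent_aperture",
    "synthesize_utterance",
    "render_lip_frames",
    "generate_corpus",
    "save_corpus",
    "load_corpus",
]


@dataclass(frozen=True)
class SynthConfig:
    n_subjects_per_class: int = 25
    utterances_per_subject: int = 10
    duration_s: float = 1.0
    effect_size: float = 1.0
    coupling_mode: str = "shared"  # or "complementary"
    snr_db: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.duration_s < 1:
            raise ValueError("duration_s must be at least 1 second")
        if self.coupling_mode not in ("shared", "complementary"):
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    label: str  # "PD" or "HC"
    modulation_depth: float  # [0, 1]; fraction of full mouth excursion retained
    jitter_level: float  # fractional period perturbation (e.g. 0.01 = 1%)
    pause_rate: float  # silent-pause events per second
    base_f0: float  # Hz


@dataclass
class UtteranceRecord:
    subject_id: str
    label: str
    utterance_id: str
    waveform: np.ndarray  # float, SAMPLE_RATE Hz
    frames: np.ndarray  # (n_frames, 50, 100) in [0, 1]
    aperture: np.ndarray  # latent trajectory in [0, 1], one value per audio sample


@dataclass
class Corpus:
    config: SynthConfig
    records: list[UtteranceRecord]
    metadata: pd.DataFrame = field(repr=False)


def sample_profiles(config: SynthConfig, rng: np.random.Generator) -> list[SubjectProfile]:
    """Draw per-subject articulatory/phonatory parameters for both classes."""
    profiles = []
    for label in ("HC", "PD"):
        for i in range(config.n_subjects_per_class):
            params = {}
            for name in _HC_MEANS:
                mean = _HC_MEANS[name]
                if label == "PD":
                    mean = mean + _PD_SHIFT[name] * config.effect_size
                params[name] = mean + _HC_SDS[name] * rng.standard_normal()
            params["modulation_depth"] = float(np.clip(params["modulation_depth"], 0.05, 0.95))
            params["jitter_level"] = float(max(params["jitter_level"], 5e-4))
            params["pause_rate"] = float(max(params["pause_rate"], 0.0))
            params["base_f0"] = float(np.clip(params["base_f0"], 80.0, 300.0))
            profiles.append(SubjectProfile(subject_id=f"{label}{i:03d}", label=label, **params))
    return profiles


def latent_aperture(duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Sum of three random-phase sinusoids in 1-4 Hz, rescaled to [0, 1]."""
    n = int(round(duration_s * SAMPLE_RATE))
    t = np.arange(n) / SAMPLE_RATE
    a = np.zeros(n)
    for _ in range(3):
        freq = rng.uniform(1.0, 4.0)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        a += amp * np.sin(2 * np.pi * freq * t + phase)
    lo, hi = a.min(), a.max()
    if hi - lo < 1e-9:
        return np.full(n, 0.5)
    return (a - lo) / (hi - lo)


def _pause_mask(n: int, pause_rate: float, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Speech-activity mask in [0, 1]: dips to 0 during pauses, 20 ms ramps.

    Every utterance carries a short (70 ms) silent lead-in and lead-out,
    as real recordings do; this guarantees at least one voicing onset and
    offset per utterance while staying below the 100 ms pause threshold.
    """
    mask = np.ones(n)
    edge = int(0.070 * SAMPLE_RATE)
    mask[:edge] = 0.0
    mask[n - edge :] = 0.0
    n_events = rng.poisson(pause_rate * duration_s)
    for _ in range(n_events):
        dur = float(np.clip(rng.normal(0.25, 0.08), 0.10, 0.50))
        start = rng.uniform(0, max(duration_s - dur, 1e-3))
        i0, i1 = int(start * SAMPLE_RATE), int((start + dur) * SAMPLE_RATE)
        mask[i0:i1] = 0.0
    ramp = int(0.020 * SAMPLE_RATE)
    kernel = np.hanning(2 * ramp + 1)
    kernel /= kernel.sum()
    mask = np.convolve(mask, kernel, mode="same")
    return np.clip(mask, 0.0, 1.0)


def _pulse_train(n: int, base_f0: float, jitter_level: float, rng: np.random.Generator) -> np.ndarray:
    """Glottal-like excitation: raised-cosine pulses with jittered periods.

    The pulse shape (squared half-sine over a 60% open phase) has a strong
    low-pass spectral tilt, so the fundamental dominates the spectrum.
    """
    if base_f0 <= 0:
        raise ValueError("base_f0 must be positive")
    wave = np.zeros(n)
    nominal = 1.0 / base_f0
    t = 0.0
    while True:
        period = nominal * (1.0 + jitter_level * rng.standard_normal())
        period = float(np.clip(period, 0.5 * nominal, 2.0 * nominal))
        start = int(round(t * SAMPLE_RATE))
        if start >= n:
            break
        width = max(int(0.6 * period * SAMPLE_RATE), 4)
        u = np.arange(min(width, n - start)) / width
        wave[start : start + len(u)] += np.sin(np.pi * u) ** 2
        t += period
    return wave


def _mouth_resonance(wave: np.ndarray, aperture: np.ndarray) -> np.ndarray:
    """Second-order resonance whose center frequency tracks mouth aperture."""
    out = np.empty_like(wave)
    block = int(0.010 * SAMPLE_RATE)
    zi = np.zeros(2)
    r = 0.96
    for lo in range(0, len(wave), block):
        hi = min(lo + block, len(wave))
        fc = 500.0 + 700.0 * float(aperture[lo:hi].mean())
        theta = 2 * np.pi * fc / SAMPLE_RATE
        b = [1.0 - r]
        a = [1.0, -2 * r * np.cos(theta), r * r]
        out[lo:hi], zi = lfilter(b, a, wave[lo:hi], zi=zi)
    return out


def synthesize_utterance(
    profile: SubjectProfile,
    duration_s: float,
    rng: np.random.Generator,
    snr_db: float = 30.0,
    coupling_mode: str = "shared",
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one utterance; returns ``(waveform, aperture)``.

    ``aperture`` is the trajectory that drives the rendered lip frames,
    sampled per audio sample.  In ``shared`` mode it also drives the audio
    envelope and closes during pauses; in ``complementary`` mode the audio
    envelope is class-neutral and pauses are audible only.
    """
    if duration_s < 1:
        raise ValueError("duration_s must be at least 1 second")
    n = int(round(duration_s * SAMPLE_RATE))
    raw = latent_aperture(duration_s, rng)
    mask = _pause_mask(n, profile.pause_rate, duration_s, rng)
    if coupling_mode == "shared":
        # hypomimia scales the opening from the closed position: both the
        # excursion and the typical opening shrink with modulation depth
        video_ap = np.clip(profile.modulation_depth * raw, 0.0, 1.0) * mask
        audio_ap = video_ap
        depth = profile.modulation_depth
    elif coupling_mode == "complementary":
        video_ap = np.clip(profile.modulation_depth * raw, 0.0, 1.0)
        audio_ap = np.clip(_NEUTRAL_MODULATION * raw, 0.0, 1.0)
        depth = _NEUTRAL_MODULATION
    else:
        raise ValueError(f"unknown coupling_mode {coupling_mode!r}")

    wave = _pulse_train(n, profile.base_f0, profile.jitter_level, rng)
    wave = _mouth_resonance(wave, audio_ap)
    wave *= 1.0 - depth * (1.0 - audio_ap)
    wave *= mask
    # remove the DC / envelope-band component of the one-sided pulse train
    # (cutoff well below any plausible F0)
    sos = butter(2, 40.0, btype="highpass", fs=SAMPLE_RATE, output="sos")
    wave = sosfilt(sos, wave)
    if np.isfinite(snr_db):
        power = float(np.mean(wave**2))
        if power > 0:
            noise_sd = np.sqrt(power / (10.0 ** (snr_db / 10.0)))
            wave = wave + noise_sd * rng.standard_normal(n)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = 0.95 * wave / peak
    return wave, video_ap


def _lip_texture(rng: np.random.Generator) -> np.ndarray:
    """Static multiplicative skin texture shared by all frames.

    Spatially smoothed, like real imagery: flat regions stay locally
    ordered instead of looking like per-pixel sensor noise.
    """
    speckle = gaussian_filter(rng.normal(0.0, 1.0, size=FRAME_SHAPE), sigma=1.5)
    speckle = 1.0 + 0.10 * speckle / max(speckle.std(), 1e-9)
    return np.clip(speckle, 0.7, 1.3)


def render_lip_frames(
    aperture: np.ndarray,
    fps: int = FPS,
    rng: np.random.Generator | None = None,
    n_frames: int | None = None,
) -> np.ndarray:
    """Render grayscale lip frames tracking an aperture trajectory.

    ``aperture`` is sampled at the audio rate; frame ``k`` uses its mean
    over wall-clock window ``[k/fps, (k+1)/fps)``.  Passing ``rng=None``
    disables per-frame translation/rotation noise and pixel noise.
    Output is ``(n_frames, 50, 100)`` in [0, 1].
    """
    aperture = np.clip(np.asarray(aperture, dtype=np.float64), 0.0, 1.0)
    duration_s = len(aperture) / SAMPLE_RATE
    if n_frames is None:
        n_frames = int(np.floor(duration_s * fps))
    per_frame = max(int(round(SAMPLE_RATE / fps)), 1)
    h, w = FRAME_SHAPE
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    texture = _lip_texture(np.random.default_rng(12345))
    frames = np.empty((n_frames, h, w))
    for k in range(n_frames):
        seg = aperture[k * per_frame : (k + 1) * per_frame]
        ap = float(seg.mean()) if len(seg) else float(aperture[-1])
        if rng is not None:
            dx, dy = rng.uniform(-1.5, 1.5, size=2)
            theta = np.deg2rad(rng.uniform(-2.0, 2.0))
        else:
            dx = dy = theta = 0.0
        cy, cx = h / 2 + dy, w / 2 + dx
        u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        img = np.full((h, w), 0.55)
        outer = (u / 42.0) ** 2 + (v / 20.0) ** 2 <= 1.0
        img[outer] = 0.35 - 0.1 * np.sqrt((u / 42.0) ** 2 + (v / 20.0) ** 2)[outer]
        half_open = 1.5 + 14.0 * ap
        inner = (u / 28.0) ** 2 + (v / half_open) ** 2 <= 1.0
        img[inner] = 0.05
        # teeth: a striped bright band at a fixed position in the upper
        # opening; visible area grows with the aperture.  Because the band
        # is spatially fixed and the opening only grows with aperture, each
        # pixel's dark/teeth state is monotone in the aperture.
        band = inner & (v >= -4.2) & (v <= -1.8)
        if band.any():
            stripes = 0.80 + 0.10 * np.sin(2 * np.pi * u / 4.0)
            img[band] = stripes[band]
        img *= texture
        if rng is not None:
            noise = gaussian_filter(rng.normal(0.0, 1.0, size=img.shape), sigma=1.0)
            img = img + 0.02 * noise / max(noise.std(), 1e-9)
        frames[k] = np.clip(img, 0.0, 1.0)
    return frames


def opening_pixel_count(frame: np.ndarray, threshold: float = 0.12) -> int:
    """Number of dark mouth-opening pixels; a simple analysis probe."""
    return int((frame < threshold).sum())


def generate_corpus(config: SynthConfig) -> Corpus:
    """Generate the full paired corpus described by ``config``.

    Deterministic: identical config (including seed) gives a bit-identical
    corpus.
    """
    root = np.random.SeedSequence(config.seed)
    profile_rng = np.random.default_rng(root.spawn(1)[0])
    profiles = sample_profiles(config, profile_rng)
    records: list[UtteranceRecord] = []
    rows = []
    utt_seeds = root.spawn(len(profiles) * config.utterances_per_subject + 1)[1:]
    idx = 0
    for profile in profiles:
        for j in range(config.utterances_per_subject):
            rng = np.random.default_rng(utt_seeds[idx])
            idx += 1
            wave, aperture = synthesize_utterance(
                profile,
                config.duration_s,
                rng,
                snr_db=config.snr_db,
                coupling_mode=config.coupling_mode,
            )
            frames = render_lip_frames(aperture, rng=rng)
            utt_id = f"{profile.subject_id}_u{j:03d}"
            records.append(
                UtteranceRecord(
                    subject_id=profile.subject_id,
                    label=profile.label,
                    utterance_id=utt_id,
                    waveform=wave,
                    frames=frames,
                    aperture=aperture,
                )
            )
            rows.append(
                {
                    "subject_id": profile.subject_id,
                    "label": profile.label,
                    "utterance_id": utt_id,
                    "n_samples": len(wave),
                    "n_frames": len(frames),
                }
            )
    metadata = pd.DataFrame(rows)
    return Corpus(config=config, records=records, metadata=metadata)


# -- disk layout: one WAV + one PNG directory per utterance + metadata CSV --
def save_corpus(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in corpus.records:
        wav_path = path / f"{rec.utterance_id}.wav"
        pcm = (np.clip(rec.waveform, -1.0, 1.0) * 32767.0).astype(np.int16)
        wavfile.write(wav_path, SAMPLE_RATE, pcm)
        frame_dir = path / f"{rec.utterance_id}_frames"
        frame_dir.mkdir(exist_ok=True)
        for k, frame in enumerate(rec.frames):
            img = Image.fromarray((np.clip(frame, 0, 1) * 255.0).round().astype(np.uint8))
            img.save(frame_dir / f"frame_{k:04d}.png")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "utterance_id": rec.utterance_id,
                "wav_path": wav_path.name,
                "frames_dir": frame_dir.name,
            }
        )
    pd.DataFrame(rows).to_csv(path / "metadata.csv", index=False)
    with open(path / "synth_config.json", "w") as fh:
        json.dump(dataclasses.asdict(corpus.config), fh, indent=2)


def load_corpus(path: str | Path) -> Corpus:
    path = Path(path)
    with open(path / "synth_config.json") as fh:
        config = SynthConfig(**json.load(fh))
    metadata = pd.read_csv(path / "metadata.csv")
    records = []
    for row in metadata.itertuples():
        rate, pcm = wavfile.read(path / row.wav_path)
        wave = pcm.astype(np.float64) / 32767.0
        frame_dir = path / row.frames_dir
        frame_files = sorted(frame_dir.glob("frame_*.png"))
        frames = np.stack(
            [np.asarray(Image.open(f), dtype=np.float64) / 255.0 for f in frame_files]
        )
        records.append(
            UtteranceRecord(
                subject_id=row.subject_id,
                label=row.label,
                utterance_id=row.utterance_id,
                waveform=wave,
                frames=frames,
                aperture=np.array([]),
            )
        )
    meta = pd.DataFrame(
        {
            "subject_id": metadata["subject_id"],
            "label": metadata["label"],
            "utterance_id": metadata["utterance_id"],
            "n_samples": [len(r.waveform) for r in records],
            "n_frames": [len(r.frames) for r in records],
        }
    )
    return Corpus(config=config, records=records, metadata=meta)
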