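"""The experiment grid: classical and deep pipelines over both streams.

Each row of the benchmark (unimodal hand-crafted features, unimodal deep
encoders, classical early/joint/late fusion, and synchronous attention
fusion in each projection direction) maps to one :class:`ExperimentSpec`.
Experiments share the speaker-independent cross-validation loop in
:mod:`parkfuse.evaluation`: ``fit`` receives training and validation
records, ``predict_subjects`` returns per-utterance (classical) or
per-segment (deep) class posteriors for the mode-vote subject decision.

Classical classification uses an RBF support-vector machine with C and
gamma grid-searched on the training folds (speaker-grouped inner CV).
Deep experiments train the encoders with Adam, batch normalization,
dropout, L2 regularization and early stopping on validation UAR.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluation import LABEL_TO_INT, MetricsReport, crossvalidate, holdout_evaluate
from .features import lbp_features as _lbp_features
from .features import (
    articulation_features,
    phonation_features,
    prosody_features,
    speech_features,
)
from .fusion import EarlyFusion, FusionModel, JointFusionModel, late_fuse
from .lip_encoder import LipEncoder, LipEncoderConfig
from .nn import TrainConfig, fit_classifier, predict_proba
from .preprocessing import segments_from_corpus, standardize_audio
from .speech_encoder import SpeechEncoder, SpeechEncoderConfig, posterior_from_logits
from .synthetic import FPS, Corpus, SynthConfig, UtteranceRecord, generate_corpus

__all__ = [
    "ExperimentSpec",
    "EXPERIMENT_GRID",
    "ClassicalExperiment",
    "DeepExperiment",
    "run_experiment",
    "small_speech_config",
    "small_lip_config",
    "fusion_ordering_study",
    "corpus_hash",
]

CLASSICAL_TECHNIQUES = {
    "prosody": ("speech",),
    "phonation": ("speech",),
    "articulation": ("speech",),
    "full": ("speech",),
    "lbp": ("lip",),
    "early": ("both",),
    "late": ("both",),
    "late_mean": ("both",),
}
DEEP_TECHNIQUES = {
    "cnn": ("speech", "lip"),
    "early": ("both",),
    "joint": ("both",),
    "late": ("both",),
    "late_mean": ("both",),
    "speech_to_lip": ("both",),
    "lip_to_speech": ("both",),
    "both_projections": ("both",),
}


@dataclass(frozen=True)
class ExperimentSpec:
    approach: str  # "classical" | "deep"
    streams: str  # "speech" | "lip" | "both"
    technique: str
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict, hash=False)

    def __post_init__(self):
        table = {"classical": CLASSICAL_TECHNIQUES, "deep": DEEP_TECHNIQUES}.get(self.approach)
        if table is None:
            raise ValueError(f"approach must be 'classical' or 'deep', got {self.approach!r}")
        valid = table.get(self.technique)
        if valid is None or self.streams not in valid:
            options = sorted(
                f"{t}/{s}" for t, ss in table.items() for s in ss
            )
            raise ValueError(
                f"invalid technique/streams {self.technique!r}/{self.streams!r} for "
                f"{self.approach}; valid combinations: {', '.join(options)}"
            )


#: one spec per benchmark row (classical table + deep table)
EXPERIMENT_GRID: list[ExperimentSpec] = [
    ExperimentSpec("classical", "lip", "lbp"),
    ExperimentSpec("classical", "speech", "prosody"),
    ExperimentSpec("classical", "speech", "phonation"),
    ExperimentSpec("classical", "speech", "articulation"),
    ExperimentSpec("classical", "speech", "full"),
    ExperimentSpec("classical", "both", "early"),
    ExperimentSpec("classical", "both", "late"),
    ExperimentSpec("classical", "both", "late_mean"),
    ExperimentSpec("deep", "lip", "cnn"),
    ExperimentSpec("deep", "speech", "cnn"),
    ExperimentSpec("deep", "both", "early"),
    ExperimentSpec("deep", "both", "joint"),
    ExperimentSpec("deep", "both", "late"),
    ExperimentSpec("deep", "both", "late_mean"),
    ExperimentSpec("deep", "both", "speech_to_lip"),
    ExperimentSpec("deep", "both", "lip_to_speech"),
    ExperimentSpec("deep", "both", "both_projections"),
]

_SPEECH_EXTRACTORS = {
    "prosody": prosody_features,
    "phonation": phonation_features,
    "articulation": articulation_features,
    "full": speech_features,
}


def small_speech_config() -> SpeechEncoderConfig:
    """Reduced-width speech geometry for desk-scale experiments."""
    return SpeechEncoderConfig(
        conv1_channels=4,
        conv1_kernel=480,
        conv1_stride=48,
        conv2_channels=8,
        conv2_kernel=120,
        conv2_stride=6,
        lstm_hidden=8,
        lstm_layers=1,
        fc_hidden=(64, 32),
        dropout=0.2,
    )


def small_lip_config() -> LipEncoderConfig:
    """Reduced-width lip geometry for desk-scale experiments.

    Frames are block-averaged to 25x50 before entering the encoder.
    """
    return LipEncoderConfig(
        input_shape=(25, 50), stem_channels=4, stage_widths=(4, 8, 16), blocks_per_stage=1, dropout=0.2
    )


class _SvmPosterior:
    """Grid-searched RBF SVM emitting posterior-like scores.

    Decision-function margins are mapped through a logistic link, which
    preserves the decision boundary and gives monotone scores for the
    late-fusion rules.
    """

    def __init__(self, groups: np.ndarray, seed: int, scale_inside: bool = True):
        steps = ([("scale", StandardScaler())] if scale_inside else []) + [
            ("svm", SVC(kernel="rbf", random_state=seed))
        ]
        self._search = GridSearchCV(
            Pipeline(steps),
            {"svm__C": [1.0, 10.0, 100.0], "svm__gamma": ["scale", 1e-3]},
            cv=GroupKFold(n_splits=min(3, len(np.unique(groups)))),
            scoring="balanced_accuracy",
        )

    def fit(self, X, y, groups):
        self._search.fit(X, y, groups=groups)
        return self

    def predict_proba(self, X) -> np.ndarray:
        margin = self._search.decision_function(X)
        p_pd = 1.0 / (1.0 + np.exp(-margin))
        return np.column_stack([1.0 - p_pd, p_pd])


def _svm_pipeline(records_groups: np.ndarray, seed: int) -> _SvmPosterior:
    return _SvmPosterior(records_groups, seed)


class ClassicalExperiment:
    """Hand-crafted features + RBF-SVM, with classical fusion variants."""

    def __init__(self, technique: str, streams: str = ""):
        self.technique = technique
        self.streams = streams
        self._speech_cache: dict[str, np.ndarray] = {}
        self._lip_cache: dict[str, np.ndarray] = {}
        self._model = None
        self._speech_model = None
        self._lip_model = None
        self._early = None

    # -- feature caching (fold-independent; scaling is fitted per fold) --
    def _speech_feats(self, recs: list[UtteranceRecord]) -> np.ndarray:
        extractor = _SPEECH_EXTRACTORS.get(self.technique, speech_features)
        out = []
        for r in recs:
            if r.utterance_id not in self._speech_cache:
                track = standardize_audio(r.waveform, 48_000)
                self._speech_cache[r.utterance_id] = extractor(track.samples)
            out.append(self._speech_cache[r.utterance_id])
        return np.stack(out)

    def _lip_feats(self, recs: list[UtteranceRecord]) -> np.ndarray:
        out = []
        for r in recs:
            if r.utterance_id not in self._lip_cache:
                self._lip_cache[r.utterance_id] = _lbp_features(r.frames)
            out.append(self._lip_cache[r.utterance_id])
        return np.stack(out)

    def fit(self, train_records, val_records, seed: int = 0) -> None:
        # the SVM tunes itself by inner grouped CV, so the validation
        # records join the training set
        recs = list(train_records) + list(val_records)
        y = np.array([LABEL_TO_INT[r.label] for r in recs])
        groups = np.array([r.subject_id for r in recs])
        if self.technique in _SPEECH_EXTRACTORS:
            X = self._speech_feats(recs)
            self._model = _svm_pipeline(groups, seed).fit(X, y, groups=groups)
        elif self.technique == "lbp":
            X = self._lip_feats(recs)
            self._model = _svm_pipeline(groups, seed).fit(X, y, groups=groups)
        elif self.technique == "early":
            self._early = EarlyFusion()
            X = self._early.fit_transform(self._speech_feats(recs), self._lip_feats(recs))
            # the early-fusion blocks are already z-scored on training folds
            self._model = _SvmPosterior(groups, seed, scale_inside=False).fit(X, y, groups=groups)
        elif self.technique in ("late", "late_mean"):
            self._speech_model = _svm_pipeline(groups, seed).fit(self._speech_feats(recs), y, groups=groups)
            self._lip_model = _svm_pipeline(groups, seed).fit(self._lip_feats(recs), y, groups=groups)
        else:
            raise ValueError(f"unknown classical technique {self.technique!r}")

    def _posteriors(self, recs: list[UtteranceRecord]) -> np.ndarray:
        if self.technique in ("late", "late_mean"):
            ps = self._speech_model.predict_proba(self._speech_feats(recs))
            pl = self._lip_model.predict_proba(self._lip_feats(recs))
            rule = "max" if self.technique == "late" else "mean"
            combined = []
            for a, b in zip(ps, pl):
                _, score = late_fuse(a, b, method=rule)
                combined.append(score / score.sum())
            return np.stack(combined)
        if self.technique == "early":
            X = self._early.transform(self._speech_feats(recs), self._lip_feats(recs))
        elif self.technique == "lbp":
            X = self._lip_feats(recs)
        else:
            X = self._speech_feats(recs)
        return self._model.predict_proba(X)

    def predict_subjects(self, records) -> dict[str, np.ndarray]:
        records = list(records)
        post = self._posteriors(records)
        out: dict[str, list[np.ndarray]] = {}
        for r, p in zip(records, post):
            out.setdefault(r.subject_id, []).append(p)
        return {sid: np.stack(ps) for sid, ps in out.items()}


class _FusionHeadTrainer:
    """Adapter that trains only the attention projections and classifier
    of a fusion model, on precomputed encoder sequences."""

    def __init__(self, fusion):
        self.fusion = fusion

    def parameters(self):
        return self.fusion.head_parameters()

    def state_dict(self):
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        for i, p in enumerate(self.parameters()):
            p.data = state[str(i)].astype(p.data.dtype).copy()

    def forward_logits(self, speech_seq, lip_seq, training=False):
        return self.fusion.forward_logits_from_sequences(speech_seq, lip_seq, training)


class DeepExperiment:
    """End-to-end encoders and their fusion variants."""

    def __init__(
        self,
        technique: str,
        streams: str = "",
        speech_config: SpeechEncoderConfig | None = None,
        lip_config: LipEncoderConfig | None = None,
        train_config: TrainConfig | None = None,
        warm_start: tuple[SpeechEncoder, LipEncoder] | None = None,
    ):
        self.technique = technique
        self.streams = streams
        self.speech_config = speech_config or SpeechEncoderConfig()
        self.lip_config = lip_config or LipEncoderConfig()
        self.train_config = train_config or TrainConfig()
        self.warm_start = warm_start
        self._seg_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.speech_model: SpeechEncoder | None = None
        self.lip_model: LipEncoder | None = None
        self.fusion_model = None
        self.histories: list = []
        self._head = None
        self._early = None

    # -- segment tensors ----------------------------------------------
    def _segments(self, recs: list[UtteranceRecord]):
        audio, frames, labels, subjects = [], [], [], []
        for r in recs:
            if r.utterance_id not in self._seg_cache:
                corpus = Corpus(config=None, records=[r], metadata=None)
                segs = segments_from_corpus(corpus)
                a = np.stack([s.audio for s in segs]).astype(np.float32)
                f = np.stack([s.frames for s in segs]).astype(np.float32)
                self._seg_cache[r.utterance_id] = (a, f)
            a, f = self._seg_cache[r.utterance_id]
            f = self._fit_frames(f)
            audio.append(a)
            frames.append(f)
            labels.extend([LABEL_TO_INT[r.label]] * len(a))
            subjects.extend([r.subject_id] * len(a))
        return (
            np.concatenate(audio),
            np.concatenate(frames),
            np.array(labels),
            np.array(subjects),
        )

    def _fit_frames(self, frames: np.ndarray) -> np.ndarray:
        """Block-average frames down to the configured lip input shape."""
        th, tw = self.lip_config.input_shape
        n, t, h, w = frames.shape
        if (h, w) == (th, tw):
            return frames
        if h % th or w % tw:
            raise ValueError(f"cannot reduce {h}x{w} frames to {th}x{tw}")
        fh, fw = h // th, w // tw
        return frames.reshape(n, t, th, fh, tw, fw).mean(axis=(3, 5), dtype=np.float32)

    def _needs_speech(self) -> bool:
        return self.technique in ("cnn", "early", "late", "late_mean") and self.streams != "lip"

    def _needs_lip(self) -> bool:
        return self.technique in ("cnn", "early", "late", "late_mean") and self.streams != "speech"

    def _encoder_sequences(self, audio: np.ndarray, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-segment encoder sequences in inference mode, batched."""
        sseq, lseq = [], []
        for lo in range(0, len(audio), 32):
            s, _ = self.speech_model.forward(audio[lo : lo + 32], training=False)
            sseq.append(s.data)
            lseq.append(self.lip_model.forward_sequence(frames[lo : lo + 32], training=False).data)
        return np.concatenate(sseq), np.concatenate(lseq)

    def _pretrain_unimodal(self, a_tr, f_tr, y_tr, a_va, f_va, y_va, tc: TrainConfig) -> None:
        self.speech_model = SpeechEncoder(self.speech_config, seed=tc.seed)
        self.histories.append(
            fit_classifier(self.speech_model, (a_tr,), y_tr, (a_va,), y_va, tc)
        )
        self.lip_model = LipEncoder(self.lip_config, seed=tc.seed + 1)
        # frame-level training with labels inherited from the subject
        fr_tr = f_tr.reshape(-1, *f_tr.shape[2:])
        fr_va = f_va.reshape(-1, *f_va.shape[2:])
        self.histories.append(
            fit_classifier(
                self.lip_model, (fr_tr,), np.repeat(y_tr, FPS), (fr_va,), np.repeat(y_va, FPS), tc
            )
        )

    def fit(self, train_records, val_records, seed: int = 0) -> None:
        tc = TrainConfig(**{**asdict(self.train_config), "seed": seed})
        a_tr, f_tr, y_tr, _ = self._segments(list(train_records))
        a_va, f_va, y_va, _ = self._segments(list(val_records))
        self.histories = []
        if self.technique in ("speech_to_lip", "lip_to_speech", "both_projections", "joint"):
            # warm-start from unimodal encoders, then fine-tune end to end
            # at a reduced learning rate
            if self.warm_start is not None:
                self.speech_model, self.lip_model = self.warm_start
            else:
                self._pretrain_unimodal(a_tr, f_tr, y_tr, a_va, f_va, y_va, tc)
            if self.technique == "joint":
                self.fusion_model = JointFusionModel(self.speech_config, self.lip_config, seed=seed)
            else:
                direction = "both" if self.technique == "both_projections" else self.technique
                self.fusion_model = FusionModel(
                    self.speech_config, self.lip_config, direction=direction, seed=seed
                )
            self.fusion_model.init_from(self.speech_model, self.lip_model)
            # stage 1: converge attention + head on cached encoder
            # sequences (cheap — the encoders are not re-run per step)
            s_tr, l_tr = self._encoder_sequences(a_tr, f_tr)
            s_va, l_va = self._encoder_sequences(a_va, f_va)
            head_tc = TrainConfig(
                epochs=150,
                batch_size=tc.batch_size,
                lr=5e-3,
                weight_decay=tc.weight_decay,
                patience=150,
                seed=seed,
            )
            self.histories.append(
                fit_classifier(
                    _FusionHeadTrainer(self.fusion_model),
                    (s_tr, l_tr),
                    y_tr,
                    (s_va, l_va),
                    y_va,
                    head_tc,
                )
            )
            # stage 2: brief end-to-end fine-tuning; the loss reaches both
            # encoders, at a strongly reduced rate so their warm-started
            # features survive
            ft = TrainConfig(
                epochs=max(tc.epochs // 5, 3),
                batch_size=tc.batch_size,
                lr=tc.lr / 10,
                weight_decay=tc.weight_decay,
                patience=tc.patience,
                seed=seed,
                slow_lr_scale=0.05,
            )
            self.histories.append(
                fit_classifier(self.fusion_model, (a_tr, f_tr), y_tr, (a_va, f_va), y_va, ft)
            )
            return
        if self._needs_speech():
            self.speech_model = SpeechEncoder(self.speech_config, seed=seed)
            self.histories.append(
                fit_classifier(self.speech_model, (a_tr,), y_tr, (a_va,), y_va, tc)
            )
        if self._needs_lip():
            self.lip_model = LipEncoder(self.lip_config, seed=seed + 1)
            fr_tr = f_tr.reshape(-1, *f_tr.shape[2:])
            fr_va = f_va.reshape(-1, *f_va.shape[2:])
            self.histories.append(
                fit_classifier(
                    self.lip_model, (fr_tr,), np.repeat(y_tr, FPS), (fr_va,), np.repeat(y_va, FPS), tc
                )
            )
        if self.technique == "early":
            # static per-segment embeddings from the frozen encoders,
            # z-scored on training data, then a linear classifier
            self._early = EarlyFusion()
            emb_tr = self._embeddings(a_tr, f_tr)
            X_tr = self._early.fit_transform(*emb_tr)
            self._head = LogisticRegression(max_iter=2000, random_state=seed)
            self._head.fit(X_tr, y_tr)

    def _embeddings(self, audio: np.ndarray, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        speech_emb, lip_emb = [], []
        for lo in range(0, len(audio), 32):
            seq, _ = self.speech_model.forward(audio[lo : lo + 32], training=False)
            speech_emb.append(seq.data.mean(axis=1))
            lseq = self.lip_model.forward_sequence(frames[lo : lo + 32], training=False)
            lip_emb.append(lseq.data.mean(axis=1))
        return np.concatenate(speech_emb), np.concatenate(lip_emb)

    def _segment_posteriors(self, audio: np.ndarray, frames: np.ndarray) -> np.ndarray:
        if self.fusion_model is not None:
            return predict_proba(self.fusion_model, (audio, frames))
        if self.technique == "early":
            X = self._early.transform(*self._embeddings(audio, frames))
            return self._head.predict_proba(X)
        speech_post = lip_post = None
        if self.speech_model is not None:
            speech_post = predict_proba(self.speech_model, (audio,))
        if self.lip_model is not None:
            flat = frames.reshape(-1, *frames.shape[2:])
            frame_post = predict_proba(self.lip_model, (flat,))
            lip_post = frame_post.reshape(len(frames), FPS, 2).mean(axis=1)
        if speech_post is not None and lip_post is not None:
            rule = "max" if self.technique == "late" else "mean"
            combined = []
            for a, b in zip(speech_post, lip_post):
                _, score = late_fuse(a, b, method=rule)
                combined.append(score / score.sum())
            return np.stack(combined)
        return speech_post if speech_post is not None else lip_post

    def predict_subjects(self, records) -> dict[str, np.ndarray]:
        audio, frames, _, subjects = self._segments(list(records))
        post = self._segment_posteriors(audio, frames)
        out: dict[str, list[np.ndarray]] = {}
        for sid, p in zip(subjects, post):
            out.setdefault(sid, []).append(p)
        return {sid: np.stack(ps) for sid, ps in out.items()}


def fusion_ordering_study(
    n_seeds: int = 10,
    effect_size: float = 1.5,
    n_subjects_per_class: int = 16,
    utterances_per_subject: int = 6,
    base_seed: int = 0,
) -> dict:
    """Multi-seed complementary-mode comparison of the deep systems.

    For each seed a fresh corpus is generated with the excursion cue
    routed to video and the jitter/pause cues to audio; the speech
    encoder, the lip encoder and the concatenated-projection fusion are
    trained on a speaker-disjoint split and scored on held-out subjects.
    Returns the per-seed subject-level UARs and their means — the
    qualitative claim under test is fusion >= each unimodal stream.
    """
    val = [f"{c}{i:03d}" for c in ("HC", "PD") for i in range(2)]
    test = [f"{c}{i:03d}" for c in ("HC", "PD") for i in range(2, n_subjects_per_class - 8)]
    tc_speech = TrainConfig(epochs=30, batch_size=32, lr=3e-3, weight_decay=1e-3, patience=30)
    tc = TrainConfig(epochs=20, batch_size=32, lr=3e-3, weight_decay=1e-3, patience=20)
    per_seed: dict[str, list[float]] = {"speech": [], "lip": [], "both": []}
    for k in range(n_seeds):
        seed = base_seed + k + 1
        corpus = generate_corpus(
            SynthConfig(
                n_subjects_per_class=n_subjects_per_class,
                utterances_per_subject=utterances_per_subject,
                duration_s=1.0,
                effect_size=effect_size,
                coupling_mode="complementary",
                seed=seed,
            )
        )
        speech_exp = DeepExperiment(
            "cnn", "speech", small_speech_config(), small_lip_config(), tc_speech
        )
        per_seed["speech"].append(
            holdout_evaluate(speech_exp, corpus, val, test, seed=seed)["uar"]
        )
        lip_exp = DeepExperiment("cnn", "lip", small_speech_config(), small_lip_config(), tc)
        per_seed["lip"].append(holdout_evaluate(lip_exp, corpus, val, test, seed=seed)["uar"])
        fusion_exp = DeepExperiment(
            "both_projections",
            "both",
            small_speech_config(),
            small_lip_config(),
            tc,
            warm_start=(speech_exp.speech_model, lip_exp.lip_model),
        )
        per_seed["both"].append(
            holdout_evaluate(fusion_exp, corpus, val, test, seed=seed)["uar"]
        )
    means = {k: float(np.mean(v)) for k, v in per_seed.items()}
    return {"means": means, "per_seed": per_seed}


def corpus_hash(corpus: Corpus) -> str:
    h = hashlib.sha256()
    h.update(corpus.metadata.to_csv(index=False).encode())
    h.update(json.dumps(asdict(corpus.config), sort_keys=True).encode())
    return h.hexdigest()[:16]


def build_experiment(spec: ExperimentSpec, desk_scale: bool = True):
    """Instantiate the runnable experiment for a grid row."""
    if spec.approach == "classical":
        return ClassicalExperiment(spec.technique, spec.streams)
    hp = dict(spec.hyperparameters)
    speech_cfg = hp.pop("speech_config", small_speech_config() if desk_scale else None)
    lip_cfg = hp.pop("lip_config", small_lip_config() if desk_scale else None)
    train_cfg = hp.pop("train_config", None)
    if train_cfg is None:
        train_cfg = TrainConfig(**hp) if hp else TrainConfig(epochs=12, lr=2e-3, patience=6)
    return DeepExperiment(spec.technique, spec.streams, speech_cfg, lip_cfg, train_cfg)


def run_experiment(
    spec: ExperimentSpec, corpus: Corpus, desk_scale: bool = True
) -> tuple[MetricsReport, dict]:
    """Execute one grid row end to end; returns (report, manifest)."""
    experiment = build_experiment(spec, desk_scale)
    report = crossvalidate(experiment, corpus, seed=spec.seed)
    manifest = {
        "spec": {
            "approach": spec.approach,
            "streams": spec.streams,
            "technique": spec.technique,
            "seed": spec.seed,
        },
        "corpus_hash": corpus_hash(corpus),
        "corpus_config": asdict(corpus.config),
        "metrics": {k: list(v) for k, v in report.aggregate().items()},
    }
    return report, manifest
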