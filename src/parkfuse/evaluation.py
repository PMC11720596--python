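"""Speaker-independent evaluation.

Experiments run 5-fold stratified cross-validation with folds assigned at
the subject level, so no speaker contributes to both training and testing.
Per-subject decisions take the mode over that subject's segment (or
utterance) predictions; reported metrics are UAR (unweighted average
recall), sensitivity (recall on PD), specificity (recall on HC) and
macro-averaged F1, in percent, as mean +/- standard deviation across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, recall_score

LABEL_TO_INT = {"HC": 0, "PD": 1}
METRIC_NAMES = ("uar", "sensitivity", "specificity", "f1")

__all__ = [
    "LABEL_TO_INT",
    "FoldPlan",
    "MetricsReport",
    "speaker_folds",
    "subject_decision",
    "compute_metrics",
    "holdout_evaluate",
    "crossvalidate",
]


@dataclass
class FoldPlan:
    folds: list[list[str]]
    seed: int
    k: int = 5

    def subjects(self) -> list[str]:
        return [s for fold in self.folds for s in fold]


@dataclass
class MetricsReport:
    per_fold: list[dict] = field(default_factory=list)

    def aggregate(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name in METRIC_NAMES:
            vals = np.array([row[name] for row in self.per_fold])
            out[name] = (float(vals.mean()), float(vals.std()))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold)

    def summary(self) -> str:
        agg = self.aggregate()
        return " | ".join(f"{k} {m:.1f} ± {s:.1f}" for k, (m, s) in agg.items())


def speaker_folds(subjects: list[str], labels: list[str], seed: int, k: int = 5) -> FoldPlan:
    """Stratified subject-level fold assignment.

    Subjects are shuffled within class and dealt round-robin into ``k``
    folds, keeping per-fold class counts within one of proportionality.
    """
    subjects = list(subjects)
    labels = list(labels)
    if len(subjects) != len(labels) or len(set(subjects)) != len(subjects):
        raise ValueError("subjects must be unique and aligned with labels")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for cls in ("PD", "HC"):
        members = [s for s, l in zip(subjects, labels) if l == cls]
        if len(members) < k:
            raise ValueError(f"need at least {k} subjects of class {cls}, got {len(members)}")
        order = rng.permutation(len(members))
        for j, idx in enumerate(order):
            folds[j % k].append(members[idx])
    return FoldPlan(folds=folds, seed=seed, k=k)


def subject_decision(segment_posteriors: np.ndarray) -> int:
    """Mode over per-segment argmax decisions; 1 = PD.

    Ties are broken by the mean PD posterior (>= 0.5 calls PD).
    """
    p = np.atleast_2d(np.asarray(segment_posteriors, dtype=np.float64))
    if p.size == 0:
        raise ValueError("no segment posteriors for subject decision")
    votes = p.argmax(axis=1)
    n_pd = int((votes == 1).sum())
    n_hc = len(votes) - n_pd
    if n_pd != n_hc:
        return int(n_pd > n_hc)
    return int(p[:, 1].mean() >= 0.5)


def compute_metrics(true_labels: np.ndarray, predicted_labels: np.ndarray) -> dict[str, float]:
    """Subject-level metrics in percent; PD (1) is the positive class."""
    y_true = np.asarray(true_labels, dtype=int)
    y_pred = np.asarray(predicted_labels, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays differ in length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present in the true labels")
    sens = recall_score(y_true, y_pred, pos_label=1, zero_division=0)
    spec = recall_score(y_true, y_pred, pos_label=0, zero_division=0)
    f1 = f1_score(y_true, y_pred, average="macro", zero_division=0)
    return {
        "uar": 100.0 * (sens + spec) / 2.0,
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * spec,
        "f1": 100.0 * f1,
    }


def holdout_evaluate(
    experiment,
    corpus,
    val_subjects: list[str],
    test_subjects: list[str],
    seed: int = 0,
) -> dict[str, float]:
    """Single speaker-disjoint train/validation/test split.

    Cheaper than full cross-validation; used for multi-seed studies where
    each repetition generates a fresh corpus.  Returns the subject-level
    metrics on the held-out test subjects.
    """
    val_set, test_set = set(val_subjects), set(test_subjects)
    if val_set & test_set:
        raise ValueError("validation and test subjects overlap")
    label_of = dict(zip(corpus.metadata["subject_id"], corpus.metadata["label"]))
    train_recs = [r for r in corpus.records if r.subject_id not in val_set | test_set]
    val_recs = [r for r in corpus.records if r.subject_id in val_set]
    test_recs = [r for r in corpus.records if r.subject_id in test_set]
    experiment.fit(train_recs, val_recs, seed=seed)
    posteriors = experiment.predict_subjects(test_recs)
    y_true = np.array([LABEL_TO_INT[label_of[s]] for s in test_subjects])
    y_pred = np.array([subject_decision(posteriors[s]) for s in test_subjects])
    return compute_metrics(y_true, y_pred)


def crossvalidate(experiment, corpus, plan: FoldPlan | None = None, seed: int = 0) -> MetricsReport:
    """Run an experiment through 5-fold speaker-independent CV.

    ``experiment`` must provide ``fit(train_records, val_records, seed)``
    and ``predict_subjects(records) -> dict[subject_id, posterior array]``.
    For each fold, one of the four training folds (rotating) is held out
    as the early-stopping/validation split; held-out subjects are scored
    by the mode rule.
    """
    meta = corpus.metadata
    subjects = meta.drop_duplicates("subject_id")
    if plan is None:
        plan = speaker_folds(subjects["subject_id"].tolist(), subjects["label"].tolist(), seed)
    plan_subjects = set(plan.subjects())
    if plan_subjects != set(subjects["subject_id"]):
        raise ValueError("fold plan does not match corpus subjects")
    by_subject = {
        sid: [r for r in corpus.records if r.subject_id == sid]
        for sid in subjects["subject_id"]
    }
    label_of = dict(zip(subjects["subject_id"], subjects["label"]))
    report = MetricsReport()
    for test_idx in range(plan.k):
        val_idx = (test_idx + 1) % plan.k
        train_ids = [
            s
            for j in range(plan.k)
            if j not in (test_idx, val_idx)
            for s in plan.folds[j]
        ]
        val_ids = list(plan.folds[val_idx])
        test_ids = list(plan.folds[test_idx])
        train_recs = [r for s in train_ids for r in by_subject[s]]
        val_recs = [r for s in val_ids for r in by_subject[s]]
        experiment.fit(train_recs, val_recs, seed=seed * 100 + test_idx)
        posteriors = experiment.predict_subjects([r for s in test_ids for r in by_subject[s]])
        y_true = np.array([LABEL_TO_INT[label_of[s]] for s in test_ids])
        y_pred = np.array([subject_decision(posteriors[s]) for s in test_ids])
        row = compute_metrics(y_true, y_pred)
        row["fold"] = test_idx
        report.per_fold.append(row)
    return report
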