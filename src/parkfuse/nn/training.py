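"""Mini-batch training with early stopping on validation UAR.

The trainer is model-agnostic: any object exposing ``forward_logits(*inputs,
training=...) -> Tensor`` of shape (N, 2), ``parameters()``, ``state_dict()``
and ``load_state_dict()`` can be fitted.  Regularization (batch
normalization, dropout, L2) lives in the models and the optimizer; the loop
adds shuffled mini-batches, per-epoch validation and best-weight restore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optim import Adam
from .tensor import softmax_cross_entropy

__all__ = ["TrainConfig", "TrainHistory", "fit_classifier", "predict_proba"]


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-4
    weight_decay: float = 1e-4
    patience: int = 10
    seed: int = 0
    #: learning-rate multiplier for parameters a model marks as "slow"
    #: (warm-started encoders during fusion fine-tuning)
    slow_lr_scale: float = 1.0


@dataclass
class TrainHistory:
    seed: int
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_uar: float = -np.inf


def _uar(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    recalls = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        recalls.append(float((y_pred[mask] == cls).mean()))
    return float(np.mean(recalls))


def predict_proba(model, inputs: tuple[np.ndarray, ...], batch_size: int = 32) -> np.ndarray:
    """Class probabilities in inference mode, computed in mini-batches."""
    n = inputs[0].shape[0]
    probs = np.empty((n, 2), dtype=np.float64)
    for lo in range(0, n, batch_size):
        batch = tuple(arr[lo : lo + batch_size] for arr in inputs)
        logits = model.forward_logits(*batch, training=False).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs[lo : lo + len(e)] = e / e.sum(axis=1, keepdims=True)
    return probs


def fit_classifier(
    model,
    train_inputs: tuple[np.ndarray, ...],
    train_labels: np.ndarray,
    val_inputs: tuple[np.ndarray, ...],
    val_labels: np.ndarray,
    config: TrainConfig,
) -> TrainHistory:
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training set contains a single class; cannot fit a classifier")
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    param_lrs = None
    if config.slow_lr_scale != 1.0 and hasattr(model, "slow_parameters"):
        slow = {id(p) for p in model.slow_parameters()}
        param_lrs = [
            config.lr * config.slow_lr_scale if id(p) in slow else config.lr for p in params
        ]
    optimizer = Adam(params, lr=config.lr, weight_decay=config.weight_decay, param_lrs=param_lrs)
    history = TrainHistory(seed=config.seed)
    best_state = model.state_dict()
    # score the starting point, so training that never helps (e.g. a
    # fine-tune of an already-good model) restores the initial weights
    init_pred = predict_proba(model, val_inputs).argmax(axis=1)
    history.best_val_uar = _uar(val_labels, init_pred)
    stale = 0
    n = train_labels.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            batch = tuple(arr[idx] for arr in train_inputs)
            if hasattr(model, "augment_batch"):
                batch = model.augment_batch(batch, rng)
            optimizer.zero_grad()
            logits = model.forward_logits(*batch, training=True)
            loss = softmax_cross_entropy(logits, train_labels[idx])
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        val_pred = predict_proba(model, val_inputs).argmax(axis=1)
        val_uar = _uar(val_labels, val_pred)
        history.epochs.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_uar": val_uar}
        )
        # ties refresh the stored weights (a flat validation curve should
        # return trained weights, not the initial state) but only a strict
        # improvement resets the patience counter, so training still halts
        if val_uar >= history.best_val_uar:
            stale = 0 if val_uar > history.best_val_uar else stale + 1
            history.best_val_uar = val_uar
            history.best_epoch = epoch
            best_state = model.state_dict()
        else:
            stale += 1
        if stale >= config.patience:
            break
    model.load_state_dict(best_state)
    return history
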