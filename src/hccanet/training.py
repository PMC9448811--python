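"""Training loop and cross-validation.

Hyperparameter defaults follow the study configuration: Adam
(β1 = 0.9, β2 = 0.99), learning rate 0.005, categorical cross-entropy,
100 epochs, batch size 32.  Epochs and batch size are routinely
overridden for desk-scale runs.  No early stopping; the best-validation
checkpoint is retained and restored at the end of training.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._engine import Adam, softmax_cross_entropy
from .metrics import MetricsReport, attach_auc, compute_metrics
from .model import HCCANet, HCCANetConfig, build_hccanet

__all__ = ["TrainConfig", "TrainingDiverged", "History", "train", "kfold_cv"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.99
    epochs: int = 100
    batch_size: int = 32
    loss: str = "categorical_crossentropy"
    # global-norm gradient clipping; stabilises the fairly aggressive
    # lr-0.005 Adam updates when training the backbone from scratch
    grad_clip_norm: float | None = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("learning_rate/epochs/batch_size must be positive")
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass
class History:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epochs,
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
        })


def _evaluate_loss_acc(model: HCCANet, X: np.ndarray, y: np.ndarray,
                       batch_size: int) -> tuple[float, float]:
    losses = []
    correct = 0
    for i in range(0, len(X), batch_size):
        xb, yb = X[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward(xb)
        loss, probs = softmax_cross_entropy(logits, yb)
        losses.append(float(loss.data) * len(xb))
        correct += int((probs.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train(model: HCCANet, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray] | None,
          cfg: TrainConfig) -> History:
    """Minibatch Adam training; returns the per-epoch history.

    When a validation set is given, the parameters of the epoch with the
    highest validation accuracy are restored into the model at the end.
    """
    X, y = train_set
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("empty training set")
    history = History()
    if cfg.epochs == 0:
        return history

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.trainable_parameters(), lr=cfg.learning_rate,
               beta1=cfg.beta1, beta2=cfg.beta2)
    best_acc = -np.inf
    best_state = None
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(X))
        ep_losses = []
        ep_correct = 0
        for i in range(0, len(X), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.forward(xb)
            loss, probs = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {i // cfg.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip_norm is not None:
                total = np.sqrt(sum(float((p.grad**2).sum())
                                    for p in opt.params if p.grad is not None))
                if total > cfg.grad_clip_norm:
                    scale = cfg.grad_clip_norm / total
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            ep_losses.append(float(loss.data) * len(xb))
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
        history.epochs.append(epoch)
        history.train_loss.append(float(np.sum(ep_losses) / len(X)))
        history.train_accuracy.append(ep_correct / len(X))
        if val_set is not None and len(val_set[0]):
            vl, va = _evaluate_loss_acc(model, np.asarray(val_set[0], dtype=np.float64),
                                        np.asarray(val_set[1], dtype=int), cfg.batch_size)
            history.val_loss.append(vl)
            history.val_accuracy.append(va)
            if va > best_acc:
                best_acc = va
                best_state = [a.copy() for a in model.state_arrays()]
                history.best_epoch = epoch
        else:
            history.val_loss.append(float("nan"))
            history.val_accuracy.append(float("nan"))
    if best_state is not None:
        model.load_state_arrays(best_state)
    return history


def kfold_cv(X: np.ndarray, y: np.ndarray, k: int = 5, *,
             model_config: HCCANetConfig, train_config: TrainConfig,
             seed: int = 0) -> tuple[list[MetricsReport], dict]:
    """Stratified k-fold cross-validation of the grading network.

    Each sample is validated exactly once.  Returns the per-fold reports
    and a summary with the mean and standard deviation of accuracy and
    macro AUC across folds.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(X) < k:
        raise ValueError(f"dataset of {len(X)} samples cannot form {k} folds")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    labels = sorted(np.unique(y).tolist())
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        cfg = copy.deepcopy(model_config)
        model = build_hccanet(cfg)
        fold_cfg = dataclasses.replace(train_config, seed=train_config.seed + fold)
        train(model, (X[tr], y[tr]), None, fold_cfg)
        probs = model.predict_proba(X[va])
        rep = compute_metrics(y[va], probs.argmax(axis=1), labels=labels)
        attach_auc(rep, y[va], probs)
        reports.append(rep)
    accs = [r.accuracy for r in reports]
    aucs = [r.macro_auc for r in reports if r.macro_auc is not None]
    summary = {
        "k": k,
        "accuracy_mean": float(np.mean(accs)),
        "accuracy_sd": float(np.std(accs)),
        "macro_auc_mean": float(np.nanmean(aucs)) if aucs else float("nan"),
        "macro_auc_sd": float(np.nanstd(aucs)) if aucs else float("nan"),
    }
    return reports, summary
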