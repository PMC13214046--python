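"""Shared supervised-training loop: BCE with logits, Adam, early stopping.

Both supervised heads (pair classifier and essentiality classifier) train
with minibatch binary cross-entropy, monitor validation AUPR after every
epoch, keep the best-AUPR parameter state, and stop after `patience` epochs
without improvement.  The held-out test split is scored exactly once, after
training, with the restored best state; the report records an audit log of
every split evaluation so leakage is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from ._autodiff import Adam, Module, Tensor

__all__ = ["aupr", "bce_with_logits", "TrainReport", "train_with_early_stopping"]


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise estimator)."""
    labels = np.asarray(labels)
    if labels.sum() < 1:
        raise ValueError("AUPR undefined without positive labels")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on raw logits."""
    y = Tensor(np.asarray(targets, dtype=np.float32).ravel())
    logits = logits.reshape(-1)
    if logits.shape != y.shape:
        raise ValueError("logits and targets must have matching lengths")
    # max(z,0) - z*y + log(1 + exp(-|z|))
    return (logits.maximum(0.0) - logits * y
            + ((-logits.abs()).exp() + 1.0).log()).mean()


@dataclass
class TrainReport:
    best_epoch: int
    best_val_aupr: float
    val_aupr_history: list[float]
    test_auc: float
    test_aupr: float
    eval_log: list[tuple[int, str]] = field(default_factory=list)

    def test_reads(self) -> list[tuple[int, str]]:
        return [e for e in self.eval_log if e[1] == "test"]


def train_with_early_stopping(
        model: Module,
        logits_fn: Callable[[Module, np.ndarray, bool], Tensor],
        y_train: np.ndarray, idx_train: np.ndarray,
        y_val: np.ndarray, idx_val: np.ndarray,
        y_test: np.ndarray, idx_test: np.ndarray,
        *, learning_rate: float = 1e-3, batch_size: int = 64,
        max_epochs: int = 100, patience: int = 10, weight_decay: float = 0.0,
        seed: int = 0) -> TrainReport:
    """Generic early-stopped binary training.

    `logits_fn(model, indices, training)` must return the logit tensor for
    the given example indices; `idx_*` address the three disjoint splits.
    """
    for name, y in (("train", y_train), ("val", y_val)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} split must contain both classes")
    rng = np.random.default_rng(seed)
    optimizer = Adam(model.parameters(), lr=learning_rate,
                     weight_decay=weight_decay)

    def split_scores(idx: np.ndarray) -> np.ndarray:
        model.eval()
        outs = []
        for lo in range(0, len(idx), 512):
            outs.append(logits_fn(model, idx[lo:lo + 512], False).data.ravel())
        return np.concatenate(outs)

    best_state = model.state_dict()
    best_val = -np.inf
    best_epoch = -1
    history: list[float] = []
    log: list[tuple[int, str]] = []

    for epoch in range(max_epochs):
        model.train()
        order = rng.permutation(len(idx_train))
        for lo in range(0, len(order), batch_size):
            sel = idx_train[order[lo:lo + batch_size]]
            logits = logits_fn(model, sel, True)
            loss = bce_with_logits(logits,
                                   y_train[order[lo:lo + batch_size]])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        val_scores = split_scores(idx_val)
        log.append((epoch, "val"))
        score = aupr(val_scores, y_val)
        history.append(score)
        if score > best_val:
            best_val = score
            best_epoch = epoch
            best_state = model.state_dict()
        elif epoch - best_epoch >= patience:
            break

    model.load_state_dict(best_state)
    model.eval()
    test_scores = split_scores(idx_test)
    log.append((best_epoch, "test"))
    return TrainReport(
        best_epoch=best_epoch, best_val_aupr=float(best_val),
        val_aupr_history=history,
        test_auc=float(roc_auc_score(y_test, test_scores))
        if len(np.unique(y_test)) > 1 else float("nan"),
        test_aupr=aupr(test_scores, y_test), eval_log=log)
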