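"""Training loops shared by the sequence classifiers and regressors.

Models expose ``layers`` (list of :class:`~imutrack.nn.layers.Layer`),
``forward(x, training, rng)`` and ``backward(dout)``.  Both loops follow
the same protocol: Adam with weight decay, global-norm gradient clipping,
and early stopping on validation loss with best-weights restore.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .layers import sigmoid
from .optim import Adam

__all__ = [
    "TrainingProtocol",
    "bce_loss",
    "train_window_classifier",
    "train_sequence_regressor",
]

EPS = 1e-7


@dataclass
class TrainingProtocol:
    """Optimizer/regularization settings used across all trained networks."""

    learning_rate: float = 5e-3
    weight_decay: float = 1e-5
    batch_size: int = 32  # 1 for the variable-length regressors
    early_stop_patience: int = 20
    max_epochs: int = 200
    gradient_clip: float = 1.0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("protocol values must be positive")
        if self.early_stop_patience < 1 or int(self.early_stop_patience) != self.early_stop_patience:
            raise ValueError("patience must be a positive integer")


def bce_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy with probability clipping."""
    p = np.clip(p, EPS, 1 - EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _snapshot(layers) -> list[dict[str, np.ndarray]]:
    return [copy.deepcopy(layer.params) for layer in layers]


def _restore(layers, snap) -> None:
    for layer, params in zip(layers, snap):
        for k in layer.params:
            layer.params[k][...] = params[k]


class _EarlyStopper:
    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_snap = None
        self.stale = 0

    def update(self, loss: float, layers) -> bool:
        """Record the epoch; return True when training should stop."""
        if loss < self.best - 1e-12:
            self.best = loss
            self.best_snap = _snapshot(layers)
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience

    def restore_best(self, layers) -> None:
        if self.best_snap is not None:
            _restore(layers, self.best_snap)


def train_window_classifier(
    model,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    protocol: TrainingProtocol,
    seed: int = 0,
) -> dict[str, list[float]]:
    """Minibatch BCE training of a window classifier emitting logits."""
    if len(x_val) == 0:
        raise ValueError("validation split is empty")
    rng = np.random.default_rng(seed)
    opt = Adam(
        model.layers,
        lr=protocol.learning_rate,
        weight_decay=protocol.weight_decay,
        clip_norm=protocol.gradient_clip,
    )
    stopper = _EarlyStopper(protocol.early_stop_patience)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    # epoch-0 baseline so warm-started weights are never discarded for worse
    stopper.update(bce_loss(y_val, model.predict_proba(x_val)), model.layers)
    n = len(x_train)
    for _ in range(protocol.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, protocol.batch_size):
            idx = order[start : start + protocol.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            opt.zero_grad()
            logits = model.forward(xb, training=True, rng=rng)
            p = np.clip(sigmoid(logits), EPS, 1 - EPS)
            epoch_loss += bce_loss(yb, p) * len(idx)
            model.backward((p - yb) / len(idx))  # dBCE/dlogit through sigmoid
            opt.step()
        history["train_loss"].append(epoch_loss / n)
        val_p = model.predict_proba(x_val)
        val_loss = bce_loss(y_val, val_p)
        history["val_loss"].append(val_loss)
        if stopper.update(val_loss, model.layers):
            break
    stopper.restore_best(model.layers)
    return history


def train_sequence_regressor(
    model,
    train_pairs: list[tuple[np.ndarray, np.ndarray]],
    val_pairs: list[tuple[np.ndarray, np.ndarray]],
    protocol: TrainingProtocol,
    seed: int = 0,
    loss_grad=None,
) -> dict[str, list[float]]:
    """Batch-size-1 MSE training over variable-length (input, target) pairs.

    ``loss_grad(y, yhat) -> (loss, dyhat)`` may be overridden (the stacked
    joint network passes its combined classification+regression loss).
    """
    if not val_pairs:
        raise ValueError("validation split is empty")

    def mse_grad(y: np.ndarray, yhat: np.ndarray):
        r = yhat - y
        loss = float(np.mean(r**2))
        return loss, 2 * r / r.size

    loss_grad = loss_grad or mse_grad
    rng = np.random.default_rng(seed)
    opt = Adam(
        model.layers,
        lr=protocol.learning_rate,
        weight_decay=protocol.weight_decay,
        clip_norm=protocol.gradient_clip,
    )
    stopper = _EarlyStopper(protocol.early_stop_patience)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    def val_loss_now() -> float:
        total = 0.0
        for x, y in val_pairs:
            total += loss_grad(y, model.forward(x[None], training=False)[0])[0]
        return total / len(val_pairs)

    # epoch-0 baseline so warm-started weights are never discarded for worse
    stopper.update(val_loss_now(), model.layers)
    for _ in range(protocol.max_epochs):
        order = rng.permutation(len(train_pairs))
        epoch_loss = 0.0
        for idx in order:
            x, y = train_pairs[idx]
            opt.zero_grad()
            yhat = model.forward(x[None], training=True, rng=rng)[0]
            loss, dy = loss_grad(y, yhat)
            epoch_loss += loss
            model.backward(dy[None])
            opt.step()
        history["train_loss"].append(epoch_loss / len(train_pairs))
        val_loss = val_loss_now()
        history["val_loss"].append(val_loss)
        if stopper.update(val_loss, model.layers):
            break
    stopper.restore_best(model.layers)
    return history
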