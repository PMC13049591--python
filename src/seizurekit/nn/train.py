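"""Seeded mini-batch training with validation-based early stopping.

The validation subset is carved from the training data by the caller (see
``seizurekit.models.train_model``); ``fit`` itself never touches test data.
Early stopping monitors validation loss and restores the best-epoch weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["sigmoid_bce", "softmax_ce", "Adam", "History", "fit"]


def sigmoid_bce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Binary cross-entropy on logits; returns (loss, dlogits, probabilities)."""
    z = logits.reshape(-1)
    yf = y.astype(float)
    # log(1 + exp(-|z|)) formulation avoids overflow
    loss = float(np.mean(np.maximum(z, 0) - z * yf + np.log1p(np.exp(-np.abs(z)))))
    p = np.empty_like(z)
    pos = z >= 0
    p[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    p[~pos] = e / (1.0 + e)
    dlogits = ((p - yf) / z.size).reshape(logits.shape)
    return loss, dlogits, p


def softmax_ce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Categorical cross-entropy on logits; returns (loss, dlogits, probs)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = z.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-300)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    return loss, dlogits, p


class Adam:
    """Adaptive-moment estimation; state keyed by parameter position."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, gr, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * gr
            v *= self.beta2
            v += (1 - self.beta2) * gr * gr
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class History:
    """Per-epoch training curves (train and validation loss/accuracy)."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.loss)


def _accuracy(probs: np.ndarray, y: np.ndarray) -> float:
    if probs.ndim == 1:
        pred = (probs >= 0.5).astype(int)
    else:
        pred = probs.argmax(axis=1)
    return float(np.mean(pred == y))


def _eval(net, loss_fn, x, y, batch_size: int) -> tuple[float, float]:
    losses, probs_all = [], []
    for start in range(0, len(x), batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        loss, _, probs = loss_fn(net.forward(xb, train=False), yb)
        losses.append(loss * len(xb))
        probs_all.append(probs)
    probs = np.concatenate(probs_all)
    return float(np.sum(losses) / len(x)), _accuracy(probs, y)


def fit(
    net,
    loss_fn,
    x: np.ndarray,
    y: np.ndarray,
    *,
    x_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int = 50,
    batch_size: int = 32,
    lr: float = 1e-3,
    patience: int = 10,
    min_delta: float = 0.0,
    seed: int = 0,
    restore_best: bool = True,
) -> History:
    """Train ``net`` with Adam and early stopping on validation loss.

    ``patience`` counts consecutive non-improving epochs tolerated before
    halting; 0 halts at the first non-improving epoch.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(lr=lr)
    hist = History()
    best_loss = np.inf
    best_weights = None
    stale = 0
    for _ in range(epochs):
        order = rng.permutation(len(x))
        ep_loss, ep_correct = 0.0, 0.0
        for start in range(0, len(x), batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], y[idx]
            logits = net.forward(xb, train=True)
            loss, dlogits, probs = loss_fn(logits, yb)
            net.zero_grad()
            net.backward(dlogits)
            opt.step(net.parameters(), net.gradients())
            ep_loss += loss * len(xb)
            ep_correct += _accuracy(probs, yb) * len(xb)
        hist.loss.append(ep_loss / len(x))
        hist.accuracy.append(ep_correct / len(x))
        val_loss, val_acc = _eval(net, loss_fn, x_val, y_val, batch_size)
        hist.val_loss.append(val_loss)
        hist.val_accuracy.append(val_acc)
        if val_loss < best_loss - min_delta:
            best_loss = val_loss
            best_weights = net.get_weights()
            stale = 0
        else:
            stale += 1
            if stale > patience:
                break
    if restore_best and best_weights is not None:
        net.set_weights(best_weights)
    return hist
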