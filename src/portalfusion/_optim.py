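"""Shared training numerics: softmax, focal/cross-entropy gradients, Adam.

All classifier heads in this package (the linear probe on frozen
encoder embeddings and the three fusion heads) are trained with the
same machinery: full-batch forward pass, an analytic gradient of the
(possibly focal, possibly example-weighted) loss with respect to the
logits, manual backpropagation through the head, and Adam updates.
Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-12


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def loss_and_grad_logits(
    logits: np.ndarray,
    y_idx: np.ndarray,
    gamma: float = 0.0,
    alpha: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean focal loss over a batch and its gradient w.r.t. the logits.

    loss_i = -alpha_i * (1 - p_t)^gamma * ln(p_t)  with  p_t = softmax(z_i)[y_i].

    gamma=0 and alpha=1 is plain cross-entropy, whose gradient reduces
    to the familiar ``probs - onehot``.  For gamma>0 the chain rule
    gives  dL/dz_j = dL/dp_t * p_t * (delta_tj - p_j)  with
    dL/dp = alpha * [gamma (1-p)^(g-1) ln p - (1-p)^g / p].
    """
    n = logits.shape[0]
    probs = softmax(logits, axis=1)
    p_t = np.clip(probs[np.arange(n), y_idx], EPS, 1.0)
    a = np.ones(n) if alpha is None else np.asarray(alpha, dtype=float)

    one_minus = 1.0 - p_t
    loss = float(np.mean(-a * one_minus**gamma * np.log(p_t)))

    if gamma == 0.0:
        dlogits = probs.copy()
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits *= a[:, None]
    else:
        dl_dp = a * (
            gamma * one_minus ** (gamma - 1.0) * np.log(p_t) - one_minus**gamma / p_t
        )
        # dp_t/dz_j = p_t * (delta_tj - p_j)
        coef = dl_dp * p_t
        dlogits = -coef[:, None] * probs
        dlogits[np.arange(n), y_idx] += coef * 1.0
    return loss, dlogits / n


@dataclass
class TrainConfig:
    """Optimizer settings for head training (full-batch Adam)."""

    lr: float = 0.05
    epochs: int = 300
    batch_size: int | None = None  # None = full batch
    seed: int = 0


class Adam:
    """Minimal Adam over a dict of named parameter arrays (in-place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.05,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class LinearSoftmaxHead:
    """Linear classifier z = X W^T + b with softmax output.

    Serves as the classification head over frozen encoder embeddings
    and as the dense layer of the average-pooling fusion strategy.
    """

    def __init__(self, dim: int, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W = rng.normal(0.0, 0.01, size=(n_classes, dim))
        self.b = np.zeros(n_classes)

    def logits(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W.T + self.b

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.logits(X), axis=1)

    def fit(
        self,
        X: np.ndarray,
        y_idx: np.ndarray,
        gamma: float = 0.0,
        alpha: np.ndarray | None = None,
        config: TrainConfig | None = None,
    ) -> list[float]:
        """Train with Adam; returns the per-epoch loss trace."""
        config = config or TrainConfig()
        opt = Adam({"W": self.W, "b": self.b}, lr=config.lr)
        rng = np.random.default_rng(config.seed)
        n = X.shape[0]
        bs = config.batch_size or n
        trace: list[float] = []
        for _ in range(config.epochs):
            order = rng.permutation(n) if bs < n else np.arange(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                loss, dlogits = loss_and_grad_logits(
                    self.logits(X[idx]), y_idx[idx], gamma,
                    None if alpha is None else alpha[idx],
                )
                opt.step({"W": dlogits.T @ X[idx], "b": dlogits.sum(axis=0)})
                epoch_loss += loss * len(idx)
            trace.append(epoch_loss / n)
        return trace
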