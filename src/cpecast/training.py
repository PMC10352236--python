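"""Training recipe: balanced cross-entropy + stochastic weight averaging.

The loss reweights the two classes by their training prevalence so each class
contributes equally in expectation (w+ = 1/2p, w- = 1/2(1-p)); this matters
because CPE bins are heavily outnumbered at small tau.  Optimization is an
Adam update at a constant learning rate wrapped in stochastic weight
averaging: from ``swa_start_epoch`` on, the end-of-epoch weights enter a
running average every ``swa_period_epochs`` epochs, and the averaged weights
are the returned model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor
from .nn.layers import Module
from .preprocessing import ForecastSample, samples_to_arrays

PROB_CLAMP = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 100
    learning_rate: float = 1e-4
    swa_start_epoch: int = 5
    swa_period_epochs: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (self.epochs >= self.swa_start_epoch >= 1):
            raise ValueError("need epochs >= swa_start_epoch >= 1")
        if self.swa_period_epochs < 1:
            raise ValueError("swa_period_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def balanced_bce(targets: np.ndarray, probabilities: np.ndarray, p: float) -> float:
    """Prevalence-balanced binary cross entropy.

    loss = -mean[ w+ y log q + w- (1-y) log(1-q) ] with w+ = 1/(2p),
    w- = 1/(2(1-p)).  At p = 0.5 this is the ordinary BCE.  Probabilities are
    clamped to [1e-7, 1-1e-7] to keep the loss finite.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("prevalence must lie strictly between 0 and 1")
    y = np.asarray(targets, dtype=float)
    q = np.clip(np.asarray(probabilities, dtype=float), PROB_CLAMP, 1 - PROB_CLAMP)
    wp, wn = 1.0 / (2.0 * p), 1.0 / (2.0 * (1.0 - p))
    return float(-(wp * y * np.log(q) + wn * (1.0 - y) * np.log(1.0 - q)).mean())


def swa_update(avg: list[np.ndarray] | None, new: list[np.ndarray],
               k: int) -> list[np.ndarray]:
    """Running mean of weight lists: avg <- (k*avg + new) / (k+1)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    if avg is None or k == 0:
        return [w.copy() for w in new]
    if len(avg) != len(new) or any(a.shape != w.shape for a, w in zip(avg, new)):
        raise ValueError("weight shape mismatch")
    return [(k * a + w) / (k + 1) for a, w in zip(avg, new)]


class Adam:
    """Standard first-order adaptive optimizer with bias correction."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def train_model(model: Module, samples: list[ForecastSample],
                config: TrainConfig, log_path=None) -> dict:
    """Train in place; the model ends up carrying the SWA-averaged weights.

    Returns a history dict with the per-epoch mean training loss and the
    number of checkpoints that entered the average.  When ``log_path`` is
    given, one line per epoch (epoch, train loss, averaged-checkpoint count)
    is appended there.
    """
    if not samples:
        raise ValueError("no training samples")
    X, Y = samples_to_arrays(samples)
    p = float(Y.mean())
    if p <= 0.0 or p >= 1.0:
        raise ValueError(
            f"degenerate training set: positive-label prevalence is {p:.3f}; "
            "balanced loss needs both classes present")
    wp, wn = 1.0 / (2.0 * p), 1.0 / (2.0 * (1.0 - p))

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = X.shape[0]
    history: list[float] = []
    swa_weights: list[np.ndarray] | None = None
    n_averaged = 0

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            yb = Tensor(Y[idx])
            probs = model.forward(X[idx])
            q = probs.clip(PROB_CLAMP, 1 - PROB_CLAMP)
            loss = -(yb * q.log() * wp
                     + (1.0 - yb) * (1.0 - q).log() * wn).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.append(epoch_loss / n_batches)
        if epoch >= config.swa_start_epoch and \
                (epoch - config.swa_start_epoch) % config.swa_period_epochs == 0:
            swa_weights = swa_update(swa_weights, model.get_weights(), n_averaged)
            n_averaged += 1
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(f"{epoch}\t{history[-1]:.6f}\t{n_averaged}\n")

    if swa_weights is not None:
        model.set_weights(swa_weights)
    return {"loss": history, "n_averaged": n_averaged, "prevalence": p}
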