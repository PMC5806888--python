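"""Feed-forward state-output network for the hybrid NN-HMM.

A small fully-connected network (canonically 132-200-100-K: spliced and
decorrelated input, two ReLU hidden layers, softmax over the K HMM state
classes) trained by mini-batch SGD with momentum on hard Viterbi state
targets.  Decoding uses scaled likelihoods: the frame posterior P(s|x) is
divided by the state prior P(s) estimated from alignment counts, which
turns the classifier output into a quantity proportional to p(x|s) that
can replace the GMM emission score.

Training follows the classic recipe: Xavier-uniform initialization, an
initial learning rate of 0.05 with momentum 0.9, mini-batches of 128, and
20 epochs; 1% of the frames are held out, and whenever held-out frame
accuracy drops at the end of an epoch the learning rate is halved.
Adaptation is plain re-training at a reduced rate (0.01, 15 epochs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MLP",
    "TrainSchedule",
    "StatePrior",
    "init_mlp",
    "train_mlp",
    "adapt_mlp",
    "state_scaled_loglik",
    "loss_and_grads",
]


@dataclass
class MLP:
    """Fully-connected ReLU network with a softmax output layer."""

    weights: list          # list of (fan_in, fan_out) arrays
    biases: list           # list of (fan_out,) arrays

    @property
    def widths(self) -> list:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def forward(self, X: np.ndarray):
        """Return (log_posteriors, activations); softmax rows sum to 1."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            if i < len(self.weights) - 1:
                h = np.maximum(z, 0.0)  # ReLU
            else:
                h = z
            acts.append(h)
        z = acts[-1]
        z = z - z.max(axis=1, keepdims=True)
        log_post = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return log_post, acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        log_post, _ = self.forward(X)
        return log_post.argmax(axis=1)

    def save(self, path) -> None:
        obj = {"weights": [w.tolist() for w in self.weights],
               "biases": [b.tolist() for b in self.biases]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path) -> "MLP":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls([np.array(w) for w in obj["weights"]],
                   [np.array(b) for b in obj["biases"]])

    def copy(self) -> "MLP":
        return MLP([w.copy() for w in self.weights], [b.copy() for b in self.biases])


def init_mlp(widths, seed: int = 0) -> MLP:
    """Xavier-uniform initialization: W ~ U(+-sqrt(6/(fan_in+fan_out))),
    biases zero; deterministic under ``seed``."""
    if len(widths) < 2 or any(w < 1 for w in widths):
        raise ValueError(f"invalid layer widths {widths}")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLP(weights, biases)


@dataclass(frozen=True)
class TrainSchedule:
    """Optimization hyperparameters."""

    learning_rate: float = 0.05
    momentum: float = 0.9
    batch_size: int = 128
    epochs: int = 20
    holdout_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")
        if min(self.learning_rate, self.momentum, self.batch_size) <= 0 and self.momentum != 0:
            raise ValueError("schedule values must be positive")


def loss_and_grads(mlp: MLP, X: np.ndarray, y: np.ndarray):
    """Mean cross-entropy on hard targets, with analytic gradients."""
    log_post, acts = mlp.forward(X)
    n = len(X)
    loss = -log_post[np.arange(n), y].mean()
    post = np.exp(log_post)
    delta = post
    delta[np.arange(n), y] -= 1.0
    delta /= n
    gw, gb = [], []
    for i in range(len(mlp.weights) - 1, -1, -1):
        a_in = acts[i]
        gw.append(a_in.T @ delta)
        gb.append(delta.sum(axis=0))
        if i > 0:
            delta = (delta @ mlp.weights[i].T) * (acts[i] > 0)
    return loss, gw[::-1], gb[::-1]


def train_mlp(X: np.ndarray, y: np.ndarray, mlp: MLP | None = None, *,
              n_classes: int | None = None, sched: TrainSchedule | None = None):
    """Mini-batch SGD with momentum and holdout-based learning-rate halving.

    Returns ``(mlp, history)``; history rows record per-epoch mean training
    loss, held-out frame accuracy, and the learning rate used.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("empty training data")
    sched = sched or TrainSchedule()
    K = n_classes if n_classes is not None else int(y.max()) + 1
    if y.min() < 0 or y.max() >= K:
        raise ValueError(f"targets must lie in [0, {K})")
    if mlp is None:
        mlp = init_mlp([X.shape[1], 200, 100, K], seed=sched.seed)
    else:
        mlp = mlp.copy()
        if mlp.widths[-1] != K:
            raise ValueError(f"network has {mlp.widths[-1]} outputs, targets need {K}")

    rng = np.random.default_rng(sched.seed & 0x7FFFFFFF)
    n_hold = max(1, int(round(sched.holdout_fraction * len(X))))
    perm = rng.permutation(len(X))
    hold, train = perm[:n_hold], perm[n_hold:]
    if len(train) == 0:
        train, hold = hold, hold
    Xh, yh = X[hold], y[hold]
    Xt, yt = X[train], y[train]

    lr = sched.learning_rate
    vel_w = [np.zeros_like(w) for w in mlp.weights]
    vel_b = [np.zeros_like(b) for b in mlp.biases]
    prev_acc = -np.inf
    history = []
    for epoch in range(sched.epochs):
        order = rng.permutation(len(Xt))
        losses = []
        for start in range(0, len(Xt), sched.batch_size):
            idx = order[start:start + sched.batch_size]
            loss, gw, gb = loss_and_grads(mlp, Xt[idx], yt[idx])
            losses.append(loss)
            for i in range(len(mlp.weights)):
                vel_w[i] = sched.momentum * vel_w[i] - lr * gw[i]
                vel_b[i] = sched.momentum * vel_b[i] - lr * gb[i]
                mlp.weights[i] = mlp.weights[i] + vel_w[i]
                mlp.biases[i] = mlp.biases[i] + vel_b[i]
        acc = float((mlp.predict(Xh) == yh).mean())
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "holdout_accuracy": acc, "lr": lr})
        if acc < prev_acc:
            lr /= 2.0
        prev_acc = acc
    return mlp, history


def adapt_mlp(mlp: MLP, X: np.ndarray, y: np.ndarray, *,
              lr: float = 0.01, epochs: int = 15, seed: int = 0):
    """User adaptation by full re-training at a reduced learning rate."""
    if len(np.atleast_2d(X)) == 0:
        raise ValueError("empty adaptation data")
    if epochs == 0:
        return mlp.copy(), []
    sched = TrainSchedule(learning_rate=lr, epochs=epochs, seed=seed)
    return train_mlp(X, y, mlp, n_classes=mlp.widths[-1], sched=sched)


@dataclass
class StatePrior:
    """State prior probabilities estimated from alignment counts."""

    probs: np.ndarray

    @classmethod
    def from_counts(cls, counts, *, floor: float = 1e-8) -> "StatePrior":
        counts = np.asarray(counts, dtype=float)
        p = counts / max(counts.sum(), 1.0)
        p = np.maximum(p, floor)
        return cls(p / p.sum())


def state_scaled_loglik(mlp: MLP, X: np.ndarray, prior: StatePrior) -> np.ndarray:
    """(T, K) hybrid pseudo log-likelihoods log P(s|x) - log P(s)."""
    if np.any(prior.probs <= 0):
        raise ValueError("state prior must be strictly positive (floor it)")
    log_post, _ = mlp.forward(X)
    return log_post - np.log(prior.probs)[None, :]
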