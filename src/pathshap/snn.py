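"""Shallow feedforward network with mask-aware online momentum training.

The classifier is a single-hidden-layer 125-10-4 network: tanh ("tansig")
hidden units and logistic-sigmoid outputs, one output per stimulus
category, trained by per-pattern (online) gradient descent with momentum
on a least-mean-squares error, E = 1/2 * sum_k (t_k - y_k)^2, against
one-hot targets.  Binary connection masks (M1, M2) ride along with the
weights: a masked connection is exactly zero and stays zero through
training, which is what makes elbow-point pruning and sparse retraining
possible without changing the training code.

Hyperparameters (learning rate, momentum) are chosen by grid search with
random restarts, selecting the network with the highest accuracy on a
held-out instance set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CATEGORIES


class DivergenceError(RuntimeError):
    """Training produced a non-finite weight update."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(
            f"non-finite weights after epoch {epoch}; "
            "lower the learning rate or momentum"
        )


@dataclass
class NetworkParams:
    """Weights, biases and connection masks of the shallow network.

    ``W1`` is n_in x n_hidden (entry [i, j] connects input i to hidden j),
    ``W2`` is n_hidden x n_out.  ``M1``/``M2`` are binary masks of matching
    shape; a zero mask entry pins the corresponding weight to exactly 0.
    Biases are never masked.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    M1: np.ndarray
    M2: np.ndarray

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        self.M1 = np.asarray(self.M1, dtype=float)
        self.M2 = np.asarray(self.M2, dtype=float)
        if self.M1.shape != self.W1.shape or self.M2.shape != self.W2.shape:
            raise ValueError("mask shapes must match weight shapes")

    @property
    def n_in(self) -> int:
        return self.W1.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[1]

    @property
    def n_out(self) -> int:
        return self.W2.shape[1]

    @property
    def n_connections(self) -> int:
        """Number of unmasked inter-node connections (biases excluded)."""
        return int(self.M1.sum() + self.M2.sum())

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy(),
            self.M1.copy(), self.M2.copy(),
        )

    def with_masks(self, M1: np.ndarray, M2: np.ndarray) -> "NetworkParams":
        """Apply new masks, zeroing the newly masked weights."""
        out = self.copy()
        out.M1 = np.asarray(M1, dtype=float)
        out.M2 = np.asarray(M2, dtype=float)
        out.W1 = out.W1 * out.M1
        out.W2 = out.W2 * out.M2
        return out

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "M1": self.M1.astype(int).tolist(),
            "M2": self.M2.astype(int).tolist(),
        }
        payload.update(extra)
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkParams":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["W1"]), np.array(d["b1"]),
            np.array(d["W2"]), np.array(d["b2"]),
            np.array(d["M1"]), np.array(d["M2"]),
        )


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float
    momentum: float
    epochs: int
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if self.learning_rate < 0 or not np.isfinite(self.learning_rate):
            raise ValueError("learning_rate must be finite and >= 0")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must be in [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def init_random(
    n_in: int = 125,
    n_hidden: int = 10,
    n_out: int = 4,
    seed: int = 0,
    scale: float = 0.5,
) -> NetworkParams:
    """Random initial field: weights and biases i.i.d. uniform on [-scale, scale]."""
    if min(n_in, n_hidden, n_out) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    u = lambda *shape: rng.uniform(-scale, scale, size=shape)
    return NetworkParams(
        W1=u(n_in, n_hidden), b1=u(n_hidden),
        W2=u(n_hidden, n_out), b2=u(n_out),
        M1=np.ones((n_in, n_hidden)), M2=np.ones((n_hidden, n_out)),
    )


def forward(
    params: NetworkParams, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activations and outputs for one instance or a batch.

    ``h = tanh(x @ (M1*W1) + b1)``, ``y = sigmoid(h @ (M2*W2) + b2)``;
    h in [-1, 1], y in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.n_in:
        raise ValueError(
            f"feature width {x.shape[-1]} != network input size {params.n_in}"
        )
    h = np.tanh(x @ (params.M1 * params.W1) + params.b1)
    z = h @ (params.M2 * params.W2) + params.b2
    y = 1.0 / (1.0 + np.exp(-z))
    return h, y


def one_hot(labels: np.ndarray, categories: tuple[str, ...] = CATEGORIES) -> np.ndarray:
    """One-hot {0,1} targets in the fixed category order."""
    index = {c: k for k, c in enumerate(categories)}
    try:
        cols = np.array([index[l] for l in labels])
    except KeyError as err:
        raise ValueError(f"unknown category label: {err.args[0]!r}") from None
    out = np.zeros((len(labels), len(categories)))
    out[np.arange(len(labels)), cols] = 1.0
    return out


def lms_error(params: NetworkParams, x: np.ndarray, t: np.ndarray) -> float:
    """Per-pattern error E = 1/2 |t - y|^2."""
    _, y = forward(params, x)
    e = y - t
    return 0.5 * float(e @ e)


def gradients(
    params: NetworkParams, x: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic masked gradients of the per-pattern LMS error.

    Returns (dE/dW1, dE/db1, dE/dW2, dE/db2); the same backpropagation
    the online trainer applies, exposed so it can be checked against
    finite differences.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    h, y = forward(params, x)
    e = y - t
    d2 = e * y * (1.0 - y)
    d1 = ((params.M2 * params.W2) @ d2) * (1.0 - h * h)
    return (
        np.outer(x, d1) * params.M1,
        d1,
        np.outer(h, d2) * params.M2,
        d2,
    )


def train(
    params: NetworkParams,
    X: np.ndarray,
    T: np.ndarray,
    cfg: TrainConfig,
) -> tuple[NetworkParams, np.ndarray]:
    """Online gradient descent with momentum on the LMS error.

    Patterns are presented one at a time (shuffled once per epoch when
    ``cfg.shuffle``); each presentation applies
    ``dw <- momentum * dw_prev - lr * dE/dw`` with E = 1/2 |t - y|^2.
    Gradients are masked, so pruned connections never move off zero.
    Returns (trained copy of ``params``, per-epoch mean LMS error trace);
    the trace is recorded, not guaranteed monotone (online updates).
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if X.shape[0] != T.shape[0]:
        raise ValueError("X and T row counts differ")
    p = params.copy()
    W1, b1, W2, b2 = p.W1, p.b1, p.W2, p.b2
    M1, M2 = p.M1, p.M2
    W1 *= M1
    W2 *= M2
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    lr, mom = cfg.learning_rate, cfg.momentum
    trace = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        err_sum = 0.0
        for i in order:
            x = X[i]
            h = np.tanh(x @ W1 + b1)  # W1 kept masked in place
            y = 1.0 / (1.0 + np.exp(-(h @ W2 + b2)))
            e = y - T[i]
            err_sum += 0.5 * float(e @ e)
            d2 = e * y * (1.0 - y)
            d1 = (W2 @ d2) * (1.0 - h * h)
            vW2 *= mom
            vW2 -= lr * (np.outer(h, d2) * M2)
            vb2 = mom * vb2 - lr * d2
            vW1 *= mom
            vW1 -= lr * (np.outer(x, d1) * M1)
            vb1 = mom * vb1 - lr * d1
            W2 += vW2
            b2 += vb2
            W1 += vW1
            b1 += vb1
        if not (
            np.isfinite(W1).all() and np.isfinite(W2).all()
            and np.isfinite(b1).all() and np.isfinite(b2).all()
        ):
            raise DivergenceError(epoch)
        trace[epoch] = err_sum / max(n, 1)
    return NetworkParams(W1, b1, W2, b2, M1, M2), trace


def predict(
    params: NetworkParams,
    X: np.ndarray,
    categories: tuple[str, ...] = CATEGORIES,
) -> np.ndarray:
    """Predicted category per instance: argmax over the outputs.

    Ties break toward the lowest output index (the first category).
    """
    _, Y = forward(params, np.atleast_2d(np.asarray(X, dtype=float)))
    return np.array([categories[k] for k in Y.argmax(axis=1)])


def accuracy(params: NetworkParams, X: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(predict(params, X) == np.asarray(labels)))


# --------------------------------------------------------------------------
# Hyperparameter search
# --------------------------------------------------------------------------


def training_lr_grid() -> list[float]:
    """Documented learning-rate search space: log10-spaced 1e-07 .. 0.9."""
    return [10.0 ** k for k in range(-7, 0)] + [0.9]


def training_momentum_grid(fine_step: float = 0.005) -> list[float]:
    """Momentum search space: 0.05..1.00 linear, finer between 0.95 and 1.00."""
    coarse = np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 3)
    fine = np.round(np.arange(0.95, 1.0 + 1e-9, fine_step), 3)
    return sorted(set(coarse.tolist()) | set(fine.tolist()))


def retraining_lr_grid() -> list[float]:
    """Retraining learning-rate space: log10-spaced 1e-09 .. 1e-04."""
    return [10.0 ** k for k in range(-9, -3)]


def retraining_momentum_grid() -> list[float]:
    """Retraining momentum space: 0.700 .. 1.000 in 0.025 steps."""
    return np.round(np.arange(0.700, 1.000 + 1e-9, 0.025), 3).tolist()


def grid_search(
    X_train: np.ndarray,
    T_train: np.ndarray,
    X_select: np.ndarray,
    labels_select: np.ndarray,
    lr_grid: list[float],
    momentum_grid: list[float],
    epochs: int,
    n_restarts: int = 1,
    seed: int = 0,
    init_scale: float = 0.5,
    n_hidden: int = 10,
    base_params: NetworkParams | None = None,
    categories: tuple[str, ...] = CATEGORIES,
) -> tuple[NetworkParams, pd.DataFrame]:
    """Train every (lr, momentum, restart) combination; keep the best.

    Each restart uses a fresh random initial field (or a copy of
    ``base_params`` when given — the sparse-retraining case, where the
    restarts differ only in presentation order).  "Best" maximizes
    accuracy on the selection instances; ties keep the first-visited
    combination.  Returns the winning network and the full search table.
    """
    if not lr_grid or not momentum_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    ss = np.random.SeedSequence(seed)
    n_combo = len(lr_grid) * len(momentum_grid) * n_restarts
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_combo)]
    rows = []
    best: tuple[float, NetworkParams] | None = None
    k = 0
    for lr in lr_grid:
        for mom in momentum_grid:
            for restart in range(n_restarts):
                init_seed, shuffle_seed = child[2 * k], child[2 * k + 1]
                k += 1
                if base_params is None:
                    start = init_random(
                        X_train.shape[1], n_hidden, T_train.shape[1],
                        seed=init_seed, scale=init_scale,
                    )
                else:
                    start = base_params.copy()
                cfg = TrainConfig(
                    learning_rate=lr, momentum=mom, epochs=epochs,
                    seed=shuffle_seed,
                )
                try:
                    trained, _ = train(start, X_train, T_train, cfg)
                except DivergenceError:
                    rows.append((lr, mom, restart, np.nan))
                    continue
                acc = accuracy(trained, X_select, labels_select)
                rows.append((lr, mom, restart, acc))
                if best is None or acc > best[0]:
                    best = (acc, trained)
    if best is None:
        raise DivergenceError(-1)
    table = pd.DataFrame(
        rows, columns=["learning_rate", "momentum", "restart", "accuracy"]
    )
    return best[1], table
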