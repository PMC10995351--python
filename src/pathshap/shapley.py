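"""Interventional Shapley-value attribution for the shallow network.

Each prediction is decomposed over its input features (the 125 ICs) or
over the 10 hidden-node activations: the Shapley value phi of feature f
is its average marginal contribution to the model output over feature
coalitions, with absent features replaced by values drawn from a
*background set* of training instances (the interventional value
function).  Attributions are additive by construction: summed over
features and added to the base value (the expected model output over the
background) they recover the model output at the instance.

Two estimators are provided: an exact subset enumerator (feasible up to
~20 features; the default for the 10 hidden nodes) and an antithetic
permutation-sampling estimator with Monte-Carlo standard errors (the
default for the 125 inputs).  Both are oracle-checkable against each
other, which is the package's cross-validation of the attribution code.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable

import numpy as np
import pandas as pd

from .snn import NetworkParams, forward
from .synthetic import CATEGORIES

ModelFn = Callable[[np.ndarray], np.ndarray]  # (m, n_feat) -> (m, n_out)

EXACT_FEATURE_LIMIT = 20


@dataclass(frozen=True)
class ShapResult:
    """Per-instance, per-feature, per-output attributions.

    ``phi`` has shape (n_instances, n_features, n_outputs); ``base`` is
    the expected model output over the background set, shape
    (n_outputs,).  ``stderr`` (same shape as ``phi``) is present for the
    sampling estimator only.
    """

    phi: np.ndarray
    base: np.ndarray
    feature_names: list[str]
    output_names: list[str]
    stderr: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long format: instance, feature, output, phi[, stderr]."""
        m, f, o = self.phi.shape
        idx = np.indices((m, f, o)).reshape(3, -1)
        out = pd.DataFrame(
            {
                "instance": idx[0],
                "feature": [self.feature_names[i] for i in idx[1]],
                "output": [self.output_names[i] for i in idx[2]],
                "phi": self.phi.ravel(),
            }
        )
        if self.stderr is not None:
            out["stderr"] = self.stderr.ravel()
        return out


def model_fn(params: NetworkParams) -> ModelFn:
    """The full network as a batch model function over input features."""

    def f(X: np.ndarray) -> np.ndarray:
        _, Y = forward(params, np.atleast_2d(np.asarray(X, dtype=float)))
        return Y

    return f


def hidden_submodel(params: NetworkParams) -> tuple[ModelFn, ModelFn]:
    """The output layer as a model over hidden activations.

    Returns ``(g, to_hidden)``: ``g(h) = sigmoid(h @ (M2*W2) + b2)`` and
    ``to_hidden(X)`` mapping input instances to their hidden activations,
    so ``g(to_hidden(X)) == model(X)`` exactly.  Use ``to_hidden`` to
    build the sub-model's background set from the input-space background.
    """
    W2 = params.M2 * params.W2
    b2 = params.b2

    def g(H: np.ndarray) -> np.ndarray:
        H = np.atleast_2d(np.asarray(H, dtype=float))
        return 1.0 / (1.0 + np.exp(-(H @ W2 + b2)))

    def to_hidden(X: np.ndarray) -> np.ndarray:
        H, _ = forward(params, np.atleast_2d(np.asarray(X, dtype=float)))
        return H

    return g, to_hidden


def draw_background(
    train_features: np.ndarray, n: int = 100, seed: int = 0
) -> np.ndarray:
    """Background/reference set: ``n`` training rows, without replacement."""
    train_features = np.asarray(train_features, dtype=float)
    if n > len(train_features):
        raise ValueError(
            f"background size {n} exceeds training set ({len(train_features)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(train_features), size=n, replace=False)
    return train_features[idx]


def shap_exact(
    model: ModelFn,
    X: np.ndarray,
    background: np.ndarray,
    feature_names: list[str] | None = None,
    output_names: list[str] | None = None,
) -> ShapResult:
    """Exact interventional Shapley values by subset enumeration.

    phi_f = sum over coalitions S not containing f of
    |S|! (n-|S|-1)! / n! * [v(S u {f}) - v(S)], with
    v(S) = mean over background rows b of model(x_S joined with b_!S).
    Enumerates all 2^n coalitions; refuses above
    ``EXACT_FEATURE_LIMIT`` features (use :func:`shap_sampling` there).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B = np.atleast_2d(np.asarray(background, dtype=float))
    m, n = X.shape
    if n > EXACT_FEATURE_LIMIT:
        raise ValueError(
            f"{n} features means 2^{n} coalitions; exact enumeration is "
            f"limited to {EXACT_FEATURE_LIMIT} — use shap_sampling instead"
        )
    n_masks = 1 << n
    bits = (np.arange(n_masks)[:, None] >> np.arange(n)) & 1  # (masks, n)
    bits = bits.astype(bool)
    popcount = bits.sum(axis=1)
    w = np.array(
        [factorial(s) * factorial(n - s - 1) / factorial(n) for s in range(n)]
    )
    n_out = np.atleast_2d(model(X[:1])).shape[1]
    phi = np.empty((m, n, n_out))
    base = None
    for r in range(m):
        x = X[r]
        # composite[mask, b, :] = x where bit set, background row elsewhere
        comp = np.where(bits[:, None, :], x[None, None, :], B[None, :, :])
        V = model(comp.reshape(n_masks * len(B), n)).reshape(n_masks, len(B), n_out)
        V = V.mean(axis=1)  # (masks, n_out)
        if base is None:
            base = V[0].copy()
        for f in range(n):
            bit = 1 << f
            without = ~bits[:, f]
            S = np.nonzero(without)[0]
            phi[r, f] = (w[popcount[S], None] * (V[S | bit] - V[S])).sum(axis=0)
    fnames = feature_names or [f"f{i + 1}" for i in range(n)]
    onames = output_names or _default_outputs(n_out)
    return ShapResult(phi=phi, base=base, feature_names=fnames, output_names=onames)


def shap_sampling(
    model: ModelFn,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 2000,
    seed: int = 0,
    antithetic: bool = True,
    feature_names: list[str] | None = None,
    output_names: list[str] | None = None,
) -> ShapResult:
    """Permutation-sampling Shapley estimator with standard errors.

    Draws random feature orderings; walking each ordering, features flip
    one at a time from background values to the instance's values, and
    the change in the background-averaged model output is the feature's
    marginal contribution.  With ``antithetic`` each drawn ordering is
    paired with its reverse (variance reduction).  Within every ordering
    the contributions telescope, so additivity holds by construction up
    to the Monte-Carlo average.  All instances share the same orderings,
    which leaves each instance's estimate unbiased.

    ``stderr`` is the per-feature standard error over sampled orderings
    (antithetic pairs counted as single samples).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B = np.atleast_2d(np.asarray(background, dtype=float))
    m, n = X.shape
    nb = len(B)
    rng = np.random.default_rng(seed)
    n_out = np.atleast_2d(model(X[:1])).shape[1]
    base = model(B).mean(axis=0)

    n_draws = (n_permutations + 1) // 2 if antithetic else n_permutations
    samples = np.zeros((n_draws, m, n, n_out))
    for d in range(n_draws):
        perm = rng.permutation(n)
        orders = [perm, perm[::-1]] if antithetic else [perm]
        for order in orders:
            Z = np.broadcast_to(B[None, :, :], (m, nb, n)).copy()
            y_prev = model(Z.reshape(m * nb, n)).reshape(m, nb, n_out).mean(axis=1)
            for f in order:
                Z[:, :, f] = X[:, None, f]
                y = model(Z.reshape(m * nb, n)).reshape(m, nb, n_out).mean(axis=1)
                samples[d, :, f] += y - y_prev
                y_prev = y
        samples[d] /= len(orders)
    phi = samples.mean(axis=0)
    if n_draws > 1:
        stderr = samples.std(axis=0, ddof=1) / np.sqrt(n_draws)
    else:
        stderr = np.zeros_like(phi)
    fnames = feature_names or [f"f{i + 1}" for i in range(n)]
    onames = output_names or _default_outputs(n_out)
    return ShapResult(
        phi=phi, base=base, feature_names=fnames, output_names=onames,
        stderr=stderr,
    )


def _default_outputs(n_out: int) -> list[str]:
    if n_out == len(CATEGORIES):
        return list(CATEGORIES)
    return [f"out{k + 1}" for k in range(n_out)]


# --------------------------------------------------------------------------
# Summaries (ranking, bar, beeswarm, partial dependence)
# --------------------------------------------------------------------------


def summarize(
    result: ShapResult,
    feature_values: np.ndarray,
    top_n: int = 20,
) -> dict[str, pd.DataFrame]:
    """Plot-ready summaries of a :class:`ShapResult` over a dataset.

    Returns:

    ``ranking``
        Per output, features ordered by decreasing mean |phi| with the
        dominant polarity (sign of mean phi; ``0`` for an all-zero
        feature) and rank, truncated to ``top_n``.
    ``bar``
        Mean |phi| per (feature, output) — polarity-free bar data.
    ``beeswarm``
        (output, feature, feature value, phi) pairs for summary plots.
    ``dependence``
        Per (feature, output): ordinary-least-squares slope of phi
        against feature value and its sign, the quantitative version of
        reading a "positive gradient" off a dependence scatter.
    """
    if result.phi.size == 0:
        raise ValueError("empty attribution result")
    V = np.atleast_2d(np.asarray(feature_values, dtype=float))
    m, n, n_out = result.phi.shape
    if V.shape != (m, n):
        raise ValueError("feature_values shape must match phi's first two axes")

    rank_rows, bar_rows, dep_rows, bee_rows = [], [], [], []
    for k, oname in enumerate(result.output_names):
        mean_abs = np.abs(result.phi[:, :, k]).mean(axis=0)
        mean_phi = result.phi[:, :, k].mean(axis=0)
        order = np.argsort(-mean_abs, kind="stable")
        for rank, f in enumerate(order[:top_n], start=1):
            polarity = 0 if mean_abs[f] == 0.0 else int(np.sign(mean_phi[f]))
            rank_rows.append(
                (oname, rank, result.feature_names[f],
                 mean_abs[f], mean_phi[f], polarity)
            )
        for f in range(n):
            bar_rows.append((oname, result.feature_names[f], mean_abs[f]))
            if np.ptp(V[:, f]) > 0:
                slope = float(np.polyfit(V[:, f], result.phi[:, f, k], 1)[0])
            else:
                slope = 0.0
            dep_rows.append(
                (oname, result.feature_names[f], slope, int(np.sign(slope)))
            )
            for r in range(m):
                bee_rows.append(
                    (oname, result.feature_names[f], V[r, f], result.phi[r, f, k])
                )
    return {
        "ranking": pd.DataFrame(
            rank_rows,
            columns=["output", "rank", "feature", "mean_abs_phi",
                     "mean_phi", "polarity"],
        ),
        "bar": pd.DataFrame(bar_rows, columns=["output", "feature", "mean_abs_phi"]),
        "dependence": pd.DataFrame(
            dep_rows, columns=["output", "feature", "slope", "gradient_sign"]
        ),
        "beeswarm": pd.DataFrame(
            bee_rows, columns=["output", "feature", "value", "phi"]
        ),
    }
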