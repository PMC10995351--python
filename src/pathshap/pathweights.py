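"""Path-weight analysis, elbow-point thresholds and sparse retraining.

For a single-hidden-layer network, the path-weight of the route
input i -> hidden j -> output k is the product of the two connection
weights along it, ``pw[i, j, k] = W1[i, j] * W2[j, k]`` — 1,250 paths per
output for the 125-10-4 architecture.  Sorted ascending per output, the
path-weight curve is tilde-shaped: a bulk of near-zero paths (which tend
to cancel the signal in the product) flanked by a few strongly negative
and strongly positive ones.  The pruning thresholds are the two *elbow
points* of each curve — found separately on the negative and positive
branches as the point of maximum perpendicular distance to the chord
joining the branch's endpoints — and only paths outside the elbows
survive.  Surviving paths induce binary connection masks under which the
pruned network is retrained (masks frozen) with its own hyperparameter
grid search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import snn
from .snn import NetworkParams
from .synthetic import CATEGORIES


class DegenerateCurveError(ValueError):
    """All curve values equal; the elbow is undefined."""


def compute_path_weights(params: NetworkParams) -> np.ndarray:
    """Path-weight tensor, shape (n_in, n_hidden, n_out).

    Exact elementwise products of the masked weights; a masked (pruned)
    connection yields zero path-weights for every path through it.
    """
    W1 = params.M1 * params.W1
    W2 = params.M2 * params.W2
    if not (np.isfinite(W1).all() and np.isfinite(W2).all()):
        raise ValueError("network weights must be finite")
    return np.einsum("ij,jk->ijk", W1, W2)


def elbow_point(sorted_values: np.ndarray) -> int:
    """Elbow of an ascending curve: farthest point from the end-to-end chord.

    The curve points (rank, value) are min-max normalized to the unit
    square on both axes (otherwise the value axis dominates), and the
    perpendicular distance from each point to the chord joining the first
    and last points is maximized; ties break toward the smallest index.
    Returns a 0-based index into ``sorted_values``.
    """
    v = np.asarray(sorted_values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError(f"need at least 3 values, got {v.shape}")
    if np.any(np.diff(v) < 0):
        raise ValueError("values must be sorted ascending")
    if v[0] == v[-1]:
        raise DegenerateCurveError("all curve values are equal")
    n = len(v)
    x = np.arange(n) / (n - 1)
    y = (v - v[0]) / (v[-1] - v[0])
    # chord runs (0,0) -> (1,1); |cross product| / |chord|
    dist = np.abs(x * (y[-1] - y[0]) - y * (x[-1] - x[0])) / np.hypot(1.0, 1.0)
    # first index within float jitter of the maximum (documented tie-break)
    return int(np.flatnonzero(dist >= dist.max() - 1e-12)[0])


@dataclass(frozen=True)
class ElbowResult:
    """Per-output elbow thresholds on the sorted path-weight curve.

    Indices are 0-based positions into ``sorted_values`` (the full
    ascending curve); the ``*_rank`` properties expose the 1-based ranks
    used in reporting.  A branch with fewer than 3 points has no elbow
    (``None``).
    """

    output: str
    sorted_values: np.ndarray
    negative_index: int | None
    positive_index: int | None

    @property
    def negative_threshold(self) -> float | None:
        if self.negative_index is None:
            return None
        return float(self.sorted_values[self.negative_index])

    @property
    def positive_threshold(self) -> float | None:
        if self.positive_index is None:
            return None
        return float(self.sorted_values[self.positive_index])

    @property
    def negative_rank(self) -> int | None:
        return None if self.negative_index is None else self.negative_index + 1

    @property
    def positive_rank(self) -> int | None:
        return None if self.positive_index is None else self.positive_index + 1


def find_elbows(pw: np.ndarray, output: int) -> ElbowResult:
    """Elbow points of one output's sorted path-weight curve.

    The n_in * n_hidden path-weights of output ``output`` are sorted
    ascending; the elbow search runs separately on the strictly negative
    prefix and the strictly positive suffix (zero-valued paths belong to
    neither branch).  Indices refer to the full sorted curve.
    """
    if not 0 <= output < pw.shape[2]:
        raise ValueError(f"output index {output} out of range")
    values = np.sort(pw[:, :, output].ravel())
    neg = values[values < 0.0]
    pos = values[values > 0.0]
    neg_idx = None
    if len(neg) >= 3:
        neg_idx = elbow_point(neg)
    pos_idx = None
    if len(pos) >= 3:
        pos_idx = (len(values) - len(pos)) + elbow_point(pos)
    name = CATEGORIES[output] if output < len(CATEGORIES) else str(output)
    return ElbowResult(
        output=name,
        sorted_values=values,
        negative_index=neg_idx,
        positive_index=pos_idx,
    )


def surviving_paths(pw: np.ndarray, elbows: list[ElbowResult]) -> np.ndarray:
    """Boolean tensor of paths outside the elbow thresholds.

    A path (i, j, k) survives iff its rank on output k's ascending curve
    is <= the negative elbow index or >= the positive elbow index.
    Zero-valued paths never survive.  A branch too small to carry an elbow
    (< 3 points) survives whole: pruning targets the near-zero bulk, and a
    one- or two-point branch is all extremes.
    """
    n_in, n_hidden, n_out = pw.shape
    if len(elbows) != n_out:
        raise ValueError("need one ElbowResult per output")
    keep = np.zeros(pw.shape, dtype=bool)
    for k, res in enumerate(elbows):
        flat = pw[:, :, k].ravel()
        order = np.argsort(flat, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(flat))
        values = flat[order]
        n_neg = int((values < 0.0).sum())
        n_zero = int((values == 0.0).sum())
        if res.negative_index is not None:
            keep_neg = ranks <= res.negative_index
        else:
            keep_neg = ranks < n_neg  # whole (tiny or empty) branch
        if res.positive_index is not None:
            keep_pos = ranks >= res.positive_index
        else:
            keep_pos = ranks >= n_neg + n_zero
        nonzero = flat != 0.0
        keep[:, :, k] = ((keep_neg | keep_pos) & nonzero).reshape(n_in, n_hidden)
    return keep


def build_prune_masks(
    pw: np.ndarray, elbows: list[ElbowResult]
) -> tuple[np.ndarray, np.ndarray]:
    """Connection masks implied by the surviving paths.

    A hidden->output connection (j, k) is kept iff some surviving path
    uses it; an input->hidden connection (i, j) is kept iff some surviving
    path through hidden node j starts at input i (minimal-removal rule —
    a kept connection pair can re-create non-surviving paths, which is
    inherent to pruning paths on a connection-structured network).
    """
    keep = surviving_paths(pw, elbows)
    M1 = keep.any(axis=2).astype(float)  # (i, j): any output
    M2 = keep.any(axis=0).astype(float)  # (j, k): any input
    return M1, M2


def path_weight_frame(
    pw: np.ndarray, keep: np.ndarray | None = None
) -> pd.DataFrame:
    """Long-format table: input, hidden, output, pathweight[, survives]."""
    n_in, n_hidden, n_out = pw.shape
    i, j, k = np.unravel_index(np.arange(pw.size), pw.shape)
    out = pd.DataFrame(
        {
            "input": [f"IC{a + 1}" for a in i],
            "hidden": [f"h{a + 1}" for a in j],
            "output": [CATEGORIES[a] if a < len(CATEGORIES) else str(a) for a in k],
            "pathweight": pw.ravel(),
        }
    )
    if keep is not None:
        out["survives"] = keep.ravel()
    return out


def format_path(ic: int, hidden: int, output: str, value: float) -> str:
    """Human-readable surviving path, e.g. ``IC47 -> h5 -> BP 0.257``."""
    return f"IC{ic + 1} → h{hidden + 1} → {output} {value:.3f}"


def prune_and_retrain(
    best_params: NetworkParams,
    masks: tuple[np.ndarray, np.ndarray],
    X_train: np.ndarray,
    T_train: np.ndarray,
    X_select: np.ndarray,
    labels_select: np.ndarray,
    lr_grid: list[float] | None = None,
    momentum_grid: list[float] | None = None,
    epochs: int = 500,
    n_restarts: int = 1,
    seed: int = 0,
) -> tuple[NetworkParams, dict]:
    """Apply pruning masks, grid-search retraining, report the three accuracies.

    The pruned network starts from the best network's surviving weights
    (masked entries zeroed) and is retrained with the masks frozen; the
    default retraining grids are log10-spaced learning rates 1e-09..1e-04
    and momenta 0.700..1.000 in 0.025 steps.  The report carries accuracy
    before pruning, right after pruning, and after retraining, plus the
    full search table and connection counts.
    """
    lr_grid = lr_grid if lr_grid is not None else snn.retraining_lr_grid()
    momentum_grid = (
        momentum_grid if momentum_grid is not None
        else snn.retraining_momentum_grid()
    )
    pruned = best_params.with_masks(*masks)
    acc_best = snn.accuracy(best_params, X_select, labels_select)
    acc_pruned = snn.accuracy(pruned, X_select, labels_select)
    retrained, table = snn.grid_search(
        X_train, T_train, X_select, labels_select,
        lr_grid=lr_grid, momentum_grid=momentum_grid,
        epochs=epochs, n_restarts=n_restarts, seed=seed,
        base_params=pruned,
    )
    acc_retrained = snn.accuracy(retrained, X_select, labels_select)
    report = {
        "accuracy_best": acc_best,
        "accuracy_pruned": acc_pruned,
        "accuracy_retrained": acc_retrained,
        "connections_before": best_params.n_connections,
        "connections_after": pruned.n_connections,
        "search_table": table,
    }
    return retrained, report
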