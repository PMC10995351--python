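"""Shallow network: forward pass, backprop, masks, search."""

import numpy as np
import pytest

from pathshap import snn
from pathshap.snn import (
    DivergenceError,
    NetworkParams,
    TrainConfig,
    accuracy,
    forward,
    gradients,
    grid_search,
    init_random,
    lms_error,
    one_hot,
    predict,
    train,
)


class TestInit:
    def test_default_architecture_connection_counts(self):
        p = init_random(125, 10, 4, seed=0, scale=0.5)
        assert p.W1.size == 1250
        assert p.W2.size == 40
        assert p.n_connections == 1290
        assert np.all(np.abs(p.W1) <= 0.5) and np.all(np.abs(p.W2) <= 0.5)

    def test_zero_scale_gives_zero_network(self):
        p = init_random(5, 3, 2, seed=0, scale=0.0)
        for arr in (p.W1, p.b1, p.W2, p.b2):
            assert np.all(arr == 0.0)

    def test_seed_determinism(self):
        a, b = (init_random(8, 3, 2, seed=42) for _ in range(2))
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.b2, b.b2)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            init_random(0, 3, 2, seed=0)


class TestForward:
    def test_zero_params_give_half_outputs(self):
        p = init_random(6, 4, 4, seed=0, scale=0.0)
        h, y = forward(p, np.zeros(6))
        np.testing.assert_array_equal(h, np.zeros(4))
        np.testing.assert_array_equal(y, 0.5 * np.ones(4))

    def test_scalar_toy_matches_hand_calculation(self):
        p = NetworkParams(
            W1=[[1.0]], b1=[0.0], W2=[[1.0]], b2=[0.0], M1=[[1.0]], M2=[[1.0]]
        )
        _, y = forward(p, np.array([1.0]))
        assert np.isclose(y[0], 1.0 / (1.0 + np.exp(-np.tanh(1.0))))

    def test_activation_ranges(self, rng):
        p = init_random(125, 10, 4, seed=1, scale=3.0)
        X = rng.normal(size=(50, 125)) * 10
        h, y = forward(p, X)
        assert np.all((h >= -1) & (h <= 1))
        assert np.all((y >= 0) & (y <= 1))

    def test_width_mismatch_rejected(self):
        p = init_random(5, 3, 2, seed=0)
        with pytest.raises(ValueError):
            forward(p, np.zeros(4))


class TestGradients:
    def test_match_central_finite_differences(self, rng):
        # 5-3-2 toy; independent oracle: central differences of the error
        p = init_random(5, 3, 2, seed=3, scale=0.8)
        x = rng.normal(size=5)
        t = np.array([1.0, 0.0])
        gW1, gb1, gW2, gb2 = gradients(p, x, t)
        eps = 1e-6

        def fd(attr, idx):
            q = p.copy()
            getattr(q, attr)[idx] += eps
            e_plus = lms_error(q, x, t)
            getattr(q, attr)[idx] -= 2 * eps
            return (e_plus - lms_error(q, x, t)) / (2 * eps)

        for attr, g in (("W1", gW1), ("b1", gb1), ("W2", gW2), ("b2", gb2)):
            for idx in np.ndindex(g.shape):
                num = fd(attr, idx)
                assert np.isclose(g[idx], num, rtol=1e-6, atol=1e-9), (attr, idx)

    def test_single_online_step_applies_gradient(self, rng):
        # momentum 0, one instance, one epoch: w' = w - lr * dE/dw
        p = init_random(4, 3, 2, seed=5)
        x = rng.normal(size=(1, 4))
        t = np.array([[0.0, 1.0]])
        lr = 1e-3
        gW1, gb1, gW2, gb2 = gradients(p, x[0], t[0])
        out, _ = train(p, x, t, TrainConfig(lr, 0.0, 1, seed=0, shuffle=False))
        np.testing.assert_allclose(out.W1, p.W1 - lr * gW1, atol=1e-12)
        np.testing.assert_allclose(out.W2, p.W2 - lr * gW2, atol=1e-12)
        np.testing.assert_allclose(out.b1, p.b1 - lr * gb1, atol=1e-12)
        np.testing.assert_allclose(out.b2, p.b2 - lr * gb2, atol=1e-12)


class TestTrain:
    def test_zero_learning_rate_changes_nothing(self, rng):
        p = init_random(6, 3, 2, seed=1)
        X = rng.normal(size=(20, 6))
        T = one_hot(
            np.array(["BP", "BI"] * 10), categories=("BP", "BI")
        )
        out, _ = train(p, X, T, TrainConfig(0.0, 0.9, 5, seed=0))
        np.testing.assert_array_equal(out.W1, p.W1)
        np.testing.assert_array_equal(out.b2, p.b2)

    def test_linearly_separable_toy_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(7)
        X = np.vstack(
            [rng.normal([2, 2], 0.5, (50, 2)), rng.normal([-2, -2], 0.5, (50, 2))]
        )
        labels = np.array(["BP"] * 50 + ["BI"] * 50)
        T = one_hot(labels, categories=("BP", "BI"))
        p = init_random(2, 3, 2, seed=0)
        out, trace = train(p, X, T, TrainConfig(0.01, 0.9, 500, seed=0))
        pred = predict(out, X, categories=("BP", "BI"))
        assert np.mean(pred == labels) == 1.0
        assert len(trace) == 500

    def test_masked_weights_stay_exactly_zero(self, rng):
        p = init_random(6, 4, 3, seed=2)
        p.M1[1, :] = 0
        p.M2[:, 2] = 0
        p.W1 *= p.M1
        p.W2 *= p.M2
        X = rng.normal(size=(30, 6))
        T = one_hot(rng.choice(["BP", "BI", "O"], 30), categories=("BP", "BI", "O"))
        out, _ = train(p, X, T, TrainConfig(0.05, 0.95, 20, seed=1))
        assert np.all(out.W1[1, :] == 0.0)
        assert np.all(out.W2[:, 2] == 0.0)
        # unmasked weights did move
        assert not np.allclose(out.W1[0], p.W1[0])

    def test_divergence_reports_epoch(self, rng):
        # a non-finite pattern poisons the updates; the trainer must
        # surface it as a divergence error naming the epoch, not run on
        p = init_random(4, 3, 2, seed=0)
        X = rng.normal(size=(10, 4))
        X[3, 1] = np.nan
        T = one_hot(np.array(["BP", "BI"] * 5), categories=("BP", "BI"))
        with pytest.raises(DivergenceError, match="epoch 0"):
            train(p, X, T, TrainConfig(0.01, 0.9, 5, seed=0))

    def test_training_is_bitwise_reproducible(self, rng):
        p = init_random(6, 3, 2, seed=9)
        X = rng.normal(size=(25, 6))
        T = one_hot(np.array(["BP", "BI"] * 12 + ["BP"]), categories=("BP", "BI"))
        cfg = TrainConfig(0.01, 0.9, 10, seed=3)
        a, ta = train(p, X, T, cfg)
        b, tb = train(p, X, T, cfg)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(ta, tb)


class TestPredict:
    def test_argmax_and_documented_tiebreak(self):
        p = init_random(3, 2, 4, seed=0, scale=0.0)
        # all outputs 0.5 -> tie broken toward the first category
        assert predict(p, np.zeros((1, 3)))[0] == "BP"

    def test_matches_brute_force_argmax(self, rng):
        p = init_random(8, 5, 4, seed=4)
        X = rng.normal(size=(20, 8))
        _, Y = forward(p, X)
        oracle = []
        for row in Y:
            best_k, best_v = 0, -np.inf
            for k, v in enumerate(row):
                if v > best_v:
                    best_k, best_v = k, v
            oracle.append(("BP", "BI", "O", "P")[best_k])
        assert list(predict(p, X)) == oracle

    def test_one_hot_rejects_unknown_label(self):
        with pytest.raises(ValueError):
            one_hot(np.array(["BP", "XX"]))


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(11)
    X = np.vstack(
        [rng.normal([1.5, 0], 0.6, (40, 2)), rng.normal([-1.5, 0], 0.6, (40, 2))]
    )
    labels = np.array(["BP"] * 40 + ["BI"] * 40)
    return X, one_hot(labels, categories=("BP", "BI")), labels


class TestGridSearch:
    def test_single_cell_grid_is_a_single_train_call(self, toy):
        X, T, labels = toy
        best, table = grid_search(
            X, T, X, labels, [0.01], [0.9], epochs=20, n_restarts=1, seed=0,
            n_hidden=3, categories=("BP", "BI"),
        )
        assert len(table) == 1
        assert table["accuracy"].iloc[0] == accuracy(
            best, X, labels
        )

    def test_best_dominates_every_table_row(self, toy):
        X, T, labels = toy
        best, table = grid_search(
            X, T, X, labels, [1e-4, 0.01], [0.5, 0.9], epochs=10,
            n_restarts=2, seed=1, n_hidden=3, categories=("BP", "BI"),
        )
        best_acc = accuracy(best, X, labels)
        assert (table["accuracy"] <= best_acc + 1e-12).all()
        assert np.isclose(table["accuracy"].max(), best_acc)

    def test_empty_grid_rejected(self, toy):
        X, T, labels = toy
        with pytest.raises(ValueError):
            grid_search(X, T, X, labels, [], [0.9], epochs=1)


class TestDocumentedSearchSpaces:
    def test_training_learning_rates_log_spaced_up_to_0p9(self):
        g = snn.training_lr_grid()
        assert g[0] == 1e-7 and g[-1] == 0.9
        assert 1e-5 in g  # the combination the original search selected
        ratios = np.diff(np.log10(g[:-1]))
        assert np.allclose(ratios, 1.0)

    def test_training_momenta_linear_with_fine_tail(self):
        g = snn.training_momentum_grid()
        assert min(g) == 0.05 and max(g) == 1.0
        assert 0.975 in g  # selected value sits in the finer 0.95-1.00 band
        assert 0.3 in g

    def test_retraining_grids(self):
        lrs = snn.retraining_lr_grid()
        assert lrs[0] == 1e-9 and lrs[-1] == 1e-4
        moms = snn.retraining_momentum_grid()
        assert moms[0] == 0.7 and moms[-1] == 1.0
        assert np.allclose(np.diff(moms), 0.025)
        assert 0.85 in moms  # the retraining combination's momentum
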