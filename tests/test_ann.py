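"""MLP surrogates: initialization, forward pass, Jacobian correctness,
Levenberg-Marquardt and Bayesian-regularization trainers, replicate
ensembles and best-model selection."""

import numpy as np
import pytest

from screwscape import ann as A
from screwscape.ann import (
    CLASSIFIER_LAYERS,
    MLPModel,
    TrainConfig,
    forward,
    init_model,
    n_parameters,
    predict_label,
    select_best,
    strain14_features,
    strain16_features,
    train_bayes_reg,
    train_lm,
    train_model,
    train_replicates,
)


class TestInit:
    def test_classifier_parameter_count(self):
        # 14*25 + 25 + 25*1 + 1
        assert n_parameters(CLASSIFIER_LAYERS) == 401

    def test_seed_reproducibility(self):
        a = init_model([4, 6, 1], seed=3)
        b = init_model([4, 6, 1], seed=3)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_distinct_seeds_differ(self):
        a = init_model([4, 6, 1], seed=3)
        b = init_model([4, 6, 1], seed=4)
        assert not np.array_equal(a.weights[0], b.weights[0])


class TestForward:
    def test_hand_computed_2_2_1_network(self):
        """Pencil-and-paper forward pass through a fixed tiny net."""
        m = init_model([2, 2, 1], seed=0)
        m.weights = [np.array([[1.0, -1.0], [0.5, 0.25]]), np.array([[2.0, -1.0]])]
        m.biases = [np.array([0.1, -0.2]), np.array([0.3])]
        x = np.array([[0.4, -0.6]])
        h1 = np.tanh(1.0 * 0.4 + (-1.0) * (-0.6) + 0.1)
        h2 = np.tanh(0.5 * 0.4 + 0.25 * (-0.6) - 0.2)
        expected = 2.0 * h1 - 1.0 * h2 + 0.3
        assert forward(m, x)[0] == pytest.approx(expected, abs=1e-14)

    def test_zero_weights_give_constant_bias(self):
        m = init_model([3, 4, 1], seed=0)
        m.weights = [np.zeros_like(w) for w in m.weights]
        m.biases = [np.zeros(4), np.array([0.7])]
        out = forward(m, np.random.default_rng(0).normal(size=(10, 3)))
        assert np.allclose(out, 0.7)

    def test_batch_invariance(self):
        m = init_model([5, 8, 1], seed=1)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(1000, 5))
        single = forward(m, X[123:124])
        batch = forward(m, X)
        assert single[0] == pytest.approx(batch[123], abs=1e-12)

    def test_shape_mismatch_rejected(self):
        m = init_model([5, 8, 1], seed=1)
        with pytest.raises(ValueError):
            forward(m, np.zeros((3, 4)))


class TestJacobian:
    def test_matches_central_finite_differences(self):
        m = init_model([3, 4, 2, 1], seed=5)
        rng = np.random.default_rng(6)
        X = rng.normal(size=(9, 3))
        w0 = A._pack(m)
        J, _ = A._jacobian(m.weights, m.biases, X)
        eps = 1e-6
        Jfd = np.empty_like(J)
        for k in range(w0.size):
            wp, wm = w0.copy(), w0.copy()
            wp[k] += eps
            wm[k] -= eps
            yp = A._forward_normed(*A._unpack(wp, m.layer_sizes), X)[-1][:, 0]
            ym = A._forward_normed(*A._unpack(wm, m.layer_sizes), X)[-1][:, 0]
            Jfd[:, k] = (yp - ym) / (2 * eps)
        assert np.max(np.abs(J - Jfd)) / np.max(np.abs(Jfd)) < 1e-6


class TestTrainLM:
    def test_solves_linear_least_squares_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = X @ [2.0, -1.0, 0.5] + 0.25
        m = init_model([3, 1], seed=1)
        m, h = train_lm(m, (X, y), None, TrainConfig(max_epochs=50))
        assert h["sse"][-1] < 1e-8

    def test_one_accepted_step_suffices_on_linear_model(self):
        """With negligible damping a linear net is solved in one step."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = X @ [1.5, -0.5] + 1.0
        m = init_model([2, 1], seed=2)
        m, h = train_lm(m, (X, y), None, TrainConfig(max_epochs=1, mu_init=1e-12))
        assert h["sse"][0] < 1e-12

    def test_huge_damping_approaches_scaled_gradient_descent(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        m = init_model([2, 3, 1], seed=3)
        w0 = A._pack(m)
        J, yhat = A._jacobian(m.weights, m.biases, X)
        g = J.T @ (y - yhat)
        mu = 1e8
        m2 = init_model([2, 3, 1], seed=3)
        m2, _ = train_lm(
            m2, (X, y), None, TrainConfig(max_epochs=1, mu_init=mu, mu_increase=10)
        )
        step = A._pack(m2) - w0
        assert np.allclose(step, g / mu, rtol=1e-3)

    def test_zero_epochs_leave_weights_unchanged(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(10, 2)), rng.normal(size=10)
        m = init_model([2, 3, 1], seed=4)
        w0 = A._pack(m).copy()
        m, _ = train_lm(m, (X, y), None, TrainConfig(max_epochs=0))
        assert np.array_equal(A._pack(m), w0)

    def test_and_gate_convergence(self):
        """A [2,4,1] net learns the AND truth table for nearly every seed."""
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0.0, 0.0, 0.0, 1.0])
        wins = 0
        for seed in range(20):
            m = init_model([2, 4, 1], seed=seed, role="classifier")
            m, _ = train_lm(m, (X, y), None, TrainConfig(max_epochs=100))
            wins += int(np.all((forward(m, X) >= 0.5) == (y == 1.0)))
        assert wins >= 18

    def test_early_stopping_restores_best_validation_weights(self):
        rng = np.random.default_rng(4)
        Xtr = rng.uniform(-1, 1, size=(15, 1))
        ytr = np.sin(3 * Xtr[:, 0]) + rng.normal(0, 0.3, 15)
        Xva = rng.uniform(-1, 1, size=(30, 1))
        yva = np.sin(3 * Xva[:, 0])
        m = init_model([1, 12, 1], seed=5)
        m, h = train_lm(m, (Xtr, ytr), (Xva, yva), TrainConfig(max_epochs=300, val_patience=5))
        final_val = float(np.sum((forward(m, Xva) - yva) ** 2))
        assert final_val == pytest.approx(min(h["val_sse"]), rel=1e-9)


class TestTrainBayesReg:
    def test_noiseless_quadratic_recovery(self):
        X = np.linspace(-1, 1, 50)[:, None]
        y = 2 * X[:, 0] ** 2 - 0.3 * X[:, 0] + 1.0
        m, _ = train_model(X, y, [1, 10, 5, 1], TrainConfig(algorithm="bayes", max_epochs=300), seed=3)
        Xh = np.linspace(-0.95, 0.95, 200)[:, None]
        yh = 2 * Xh[:, 0] ** 2 - 0.3 * Xh[:, 0] + 1.0
        pred = forward(m, Xh)
        r2 = 1 - np.sum((pred - yh) ** 2) / np.sum((yh - yh.mean()) ** 2)
        assert r2 > 0.999

    def test_constant_target_collapses_weights(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 2))
        y = np.full(30, 5.0)
        m, _ = train_model(X, y, [2, 5, 1], TrainConfig(algorithm="bayes", max_epochs=200), seed=6)
        w_nonbias = np.concatenate([w.ravel() for w in m.weights])
        assert np.linalg.norm(w_nonbias) < 1e-3
        assert np.allclose(forward(m, X), 5.0, atol=1e-6)

    def test_evidence_quantities_stay_in_range(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-1, 1, size=(40, 1))
        y = np.sin(2 * X[:, 0]) + rng.normal(0, 0.1, 40)
        m, h = train_model(X, y, [1, 6, 1], TrainConfig(algorithm="bayes", max_epochs=100), seed=8)
        Nw = n_parameters([1, 6, 1])
        for g, a, b in zip(h["gamma"][3:], h["alpha"][3:], h["beta"][3:]):
            assert 0.0 < g < Nw
            assert a > 0 and b > 0

    def test_regularization_beats_plain_lm_on_noisy_toy(self):
        """Paired over seeds: held-out SSE of the regularized fit is lower."""
        sse_b, sse_l = [], []
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            Xtr = r.uniform(-1, 1, (20, 1))
            ytr = np.sin(2.5 * Xtr[:, 0]) + r.normal(0, 0.15, 20)
            Xte = r.uniform(-1, 1, (200, 1))
            yte = np.sin(2.5 * Xte[:, 0])
            mb, _ = train_model(Xtr, ytr, [1, 10, 1], TrainConfig(algorithm="bayes", max_epochs=150), seed=seed)
            ml, _ = train_model(Xtr, ytr, [1, 10, 1], TrainConfig(algorithm="lm", max_epochs=150), seed=seed)
            sse_b.append(np.sum((forward(mb, Xte) - yte) ** 2))
            sse_l.append(np.sum((forward(ml, Xte) - yte) ** 2))
        assert np.mean(sse_b) <= np.mean(sse_l)


class TestReplicates:
    def _toy(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(60, 2))
        y = X[:, 0] ** 2 + 0.5 * X[:, 1]
        return X, y

    def test_single_replicate_ensemble(self):
        X, y = self._toy()
        ens = train_replicates(
            X, y, [2, 4, 1], TrainConfig(algorithm="bayes", max_epochs=50), X, y,
            n_replicates=1, base_seed=0,
        )
        assert len(ens.models) == 1
        assert select_best(ens) is ens.models[0]

    def test_identical_seed_list_reproduces_metrics(self):
        X, y = self._toy()
        kw = dict(n_replicates=3, base_seed=7)
        e1 = train_replicates(X, y, [2, 4, 1], TrainConfig(algorithm="bayes", max_epochs=50), X, y, **kw)
        e2 = train_replicates(X, y, [2, 4, 1], TrainConfig(algorithm="bayes", max_epochs=50), X, y, **kw)
        assert e1.metrics == e2.metrics and e1.seeds == e2.seeds

    def test_tie_breaks_to_lowest_replicate_index(self):
        m1 = init_model([2, 2, 1], seed=0)
        m2 = init_model([2, 2, 1], seed=1)
        ens = A.ReplicateEnsemble(
            models=[m1, m2],
            metrics=[{"rmse": 1.0}, {"rmse": 1.0}],
            seeds=[0, 1],
            failures=[],
            metric_name="rmse",
        )
        assert select_best(ens) is m1

    def test_best_selection_prefers_perfect_classifier(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 2))
        y = (X[:, 0] > 0).astype(float)
        good = init_model([2, 2, 1], seed=0, role="classifier")
        good.weights = [np.array([[50.0, 0.0], [0.0, 1.0]]), np.array([[1.0, 0.0]])]
        good.biases = [np.zeros(2), np.array([0.5])]
        bad = init_model([2, 2, 1], seed=1, role="classifier")
        ens = A.ReplicateEnsemble(
            models=[bad, good],
            metrics=[
                {"accuracy": A._metric_value(bad, X, y, "accuracy")},
                {"accuracy": A._metric_value(good, X, y, "accuracy")},
            ],
            seeds=[0, 1],
            failures=[],
            metric_name="accuracy",
        )
        assert ens.metrics[1]["accuracy"] == 100.0
        assert select_best(ens) is good


class TestFeatureBuilders:
    def test_strain16_shape_and_one_hot(self):
        angles = np.zeros((4, 14))
        flags = np.array([0, 1, 1, 0])
        X = strain16_features(angles, flags)
        assert X.shape == (4, 16)
        assert np.array_equal(X[:, 14], flags)
        assert np.array_equal(X[:, 15], 1 - flags)

    def test_strain14_passthrough(self):
        angles = np.arange(28.0).reshape(2, 14)
        assert np.array_equal(strain14_features(angles), angles)
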