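"""Rprop-MLP training, grid selection, and RBF-SVM behaviour."""

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize
from sklearn.metrics import roc_auc_score

from mammica.classify import (
    MLPModel,
    RpropState,
    grid_select_mlp,
    rprop_step,
    score,
    train_mlp,
    train_svm_grid,
)

XOR_X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
XOR_Y = np.array([0.0, 1.0, 1.0, 0.0])


def blobs(seed, n=100, sep=4.0, d=5):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(sep, 1, (n, d))])
    y = np.r_[np.zeros(n), np.ones(n)]
    idx = rng.permutation(2 * n)
    return X[idx], y[idx]


class TestRprop:
    def test_steps_stay_clamped_under_random_gradients(self, rng):
        params = {"w": rng.standard_normal(20)}
        state = RpropState.init(params)
        for _ in range(300):
            grads = {"w": rng.standard_normal(20) * 10.0 ** int(rng.integers(-6, 6))}
            rprop_step(params, grads, state)
            assert (state.step["w"] >= state.delta_min - 1e-18).all()
            assert (state.step["w"] <= state.delta_max + 1e-18).all()

    def test_persistent_sign_grows_step_flip_shrinks(self):
        params = {"w": np.zeros(1)}
        state = RpropState.init(params)
        for _ in range(5):
            rprop_step(params, {"w": np.ones(1)}, state)
        grown = state.step["w"][0]
        assert grown == pytest.approx(0.1 * 1.2**4)
        rprop_step(params, {"w": -np.ones(1)}, state)
        assert state.step["w"][0] == pytest.approx(grown * 0.5)


class TestTrainMlp:
    def test_xor_solved_by_most_seeds(self):
        solved = 0
        for seed in range(5):
            model = train_mlp(XOR_X, XOR_Y, XOR_X, XOR_Y, 4, seed=seed,
                              max_epochs=500, patience=500)
            solved += (((model.score(XOR_X) > 0.5) == XOR_Y).all())
        assert solved >= 3

    def test_separable_blobs_validation_auc(self):
        X, y = blobs(0)
        model = train_mlp(X[:150], y[:150], X[150:], y[150:], 50, seed=0, max_epochs=300)
        assert roc_auc_score(y[150:], model.score(X[150:])) > 0.99

    def test_shuffled_labels_near_chance(self):
        X, y = blobs(1)
        rng = np.random.default_rng(0)
        aucs = []
        for k in range(10):
            ys = y[rng.permutation(len(y))]
            model = train_mlp(X[:150], ys[:150], X[150:], ys[150:], 10, seed=k,
                              max_epochs=100, patience=10)
            aucs.append(roc_auc_score(ys[150:], model.score(X[150:])))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_single_class_train_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="both classes"):
            train_mlp(X, np.zeros(10), X, np.zeros(10), 4)

    def test_returned_weights_are_best_validation_epoch(self):
        X, y = blobs(2, n=40)
        model = train_mlp(X[:60], y[:60], X[60:], y[60:], 20, seed=0,
                          max_epochs=200, patience=15)
        log = model.train_log
        assert log["best_epoch"] <= log["n_epochs_run"]
        # recompute validation loss of the returned weights
        p = model.score(X[60:])
        eps = 1e-12
        val = -np.mean(y[60:] * np.log(p + eps) + (1 - y[60:]) * np.log(1 - p + eps))
        assert val == pytest.approx(log["best_val_loss"], abs=1e-10)

    def test_zero_weight_net_scores_half(self):
        model = MLPModel(W1=np.zeros((3, 4)), b1=np.zeros(4),
                         W2=np.zeros((4, 1)), b2=np.zeros(1))
        np.testing.assert_allclose(model.score(np.random.default_rng(0).normal(size=(7, 3))), 0.5)


class TestGridSelectMlp:
    def test_stubbed_metric_drives_selection(self):
        X, y = blobs(3, n=30)
        clf = grid_select_mlp(
            X[:40], y[:40], X[40:], y[40:],
            hidden_grid=(50, 100, 150), restarts=2, max_epochs=5,
            metric=lambda model, Xv, yv: 1.0 if model.n_hidden == 100 else 0.5,
        )
        assert clf.selection["n_hidden"] == 100

    def test_ties_break_to_smallest_hidden_and_restart(self):
        X, y = blobs(4, n=30)
        clf = grid_select_mlp(
            X[:40], y[:40], X[40:], y[40:],
            hidden_grid=(50, 100), restarts=3, max_epochs=5,
            metric=lambda *a: 0.7,
        )
        assert clf.selection["n_hidden"] == 50 and clf.selection["restart"] == 0

    def test_deterministic_selection_across_runs(self):
        X, y = blobs(5, n=40)
        kw = dict(hidden_grid=(50, 100), restarts=2, seed=9, max_epochs=40, patience=10)
        a = grid_select_mlp(X[:60], y[:60], X[60:], y[60:], **kw)
        b = grid_select_mlp(X[:60], y[:60], X[60:], y[60:], **kw)
        assert a.selection == b.selection
        np.testing.assert_array_equal(a.model.W1, b.model.W1)

    def test_single_point_grid_equals_train_mlp(self):
        X, y = blobs(6, n=40)
        clf = grid_select_mlp(X[:60], y[:60], X[60:], y[60:],
                              hidden_grid=(50,), restarts=1, seed=4,
                              max_epochs=50, standardize=False)
        derived_seed = int(np.random.SeedSequence([4, 0x313]).generate_state(1)[0] % 2**31)
        direct = train_mlp(X[:60], y[:60], X[60:], y[60:], 50, seed=derived_seed,
                           max_epochs=50)
        np.testing.assert_array_equal(clf.model.W1, direct.W1)


def dual_qp_rbf_svm(X, y, C, gamma):
    """Brute-force soft-margin dual solve (SLSQP) for a tiny RBF SVM."""
    ys = 2.0 * y - 1.0
    K = np.exp(-gamma * ((X[:, None] - X[None]) ** 2).sum(-1))
    Q = np.outer(ys, ys) * K
    n = len(y)

    def negdual(a):
        return 0.5 * a @ Q @ a - a.sum()

    res = minimize(
        negdual, np.full(n, C / 10), jac=lambda a: Q @ a - 1,
        bounds=[(0, C)] * n,
        constraints=[LinearConstraint(ys, 0, 0)],
        method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
    )
    a = res.x
    sv = (a > 1e-8) & (a < C - 1e-8)
    b = np.mean([ys[i] - (a * ys) @ K[i] for i in np.where(sv)[0]])

    def decision(Xt):
        Kt = np.exp(-gamma * ((Xt[:, None] - X[None]) ** 2).sum(-1))
        return Kt @ (a * ys) + b

    return decision


class TestSvm:
    def test_separable_toy_zero_training_error_at_large_C(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 3.0], [3.0, 4.0]])
        y = np.array([0, 0, 1, 1])
        clf = train_svm_grid(X, y, X, y, gamma_grid=(0.5,), C_grid=(1e3,),
                             standardize=False)
        assert ((score(clf, X) > 0) == y.astype(bool)).all()

    def test_dual_solution_matches_qp_oracle(self):
        X = np.array([[0.0, 0.0], [1.0, 0.2], [0.3, 1.1],
                      [2.5, 2.4], [3.2, 2.1], [2.2, 3.3]])
        y = np.array([0, 0, 0, 1, 1, 1])
        C, gamma = 2.0, 0.5
        clf = train_svm_grid(X, y, X, y, gamma_grid=(gamma,), C_grid=(C,),
                             tol=1e-8, standardize=False)
        oracle = dual_qp_rbf_svm(X, y, C, gamma)
        Xt = np.array([[0.5, 0.5], [1.5, 1.5], [2.8, 2.8], [0.0, 3.0]])
        np.testing.assert_allclose(score(clf, Xt), oracle(Xt), atol=1e-4)

    def test_margin_support_vectors_score_plus_minus_one(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 3.0], [3.0, 4.0]])
        y = np.array([0, 0, 1, 1])
        clf = train_svm_grid(X, y, X, y, gamma_grid=(0.1,), C_grid=(1e3,),
                             tol=1e-8, standardize=False)
        s = np.abs(score(clf, X))
        assert np.isclose(s.min(), 1.0, atol=1e-3)

    def test_label_swap_negates_decision_scores(self):
        X, y = blobs(7, n=30, sep=2.0)
        kw = dict(gamma_grid=(0.25,), C_grid=(2.0,), tol=1e-8, standardize=False)
        a = train_svm_grid(X[:40], y[:40], X[40:], y[40:], **kw)
        b = train_svm_grid(X[:40], 1 - y[:40], X[40:], 1 - y[40:], **kw)
        np.testing.assert_allclose(score(a, X[40:]), -score(b, X[40:]), atol=1e-5)

    def test_single_class_and_empty_grid_rejected(self):
        X = np.zeros((8, 2))
        with pytest.raises(ValueError, match="both classes"):
            train_svm_grid(X, np.zeros(8), X, np.zeros(8))
        X, y = blobs(8, n=10)
        with pytest.raises(ValueError, match="grid"):
            train_svm_grid(X, y, X, y, gamma_grid=(), C_grid=(1.0,))
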