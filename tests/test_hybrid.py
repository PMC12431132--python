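"""SVM head: toy geometry, kernels, grid search, brute-force dual oracle."""

import numpy as np
import pytest
from scipy.optimize import linprog, minimize
from sklearn.metrics.pairwise import pairwise_kernels

from drowsyeeg.hybrid import (
    DEFAULT_GRID,
    SVMConfig,
    fit_svm,
    grid_search,
    predict,
)

XOR_X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
XOR_Y = np.array([0, 0, 1, 1])


def brute_force_dual(X, y, C, kernel):
    """Numerical solver of the soft-margin dual (the oracle).

    Maximizes sum(a) - 0.5 aT (yyT*K) a s.t. 0 <= a <= C, sum(a*y) = 0,
    via SLSQP, then recovers the bias from on-margin support vectors.
    Returns the decision function values on X.
    """
    ys = np.where(y == 1, 1.0, -1.0)
    K = pairwise_kernels(X, metric=kernel.metric, **kernel.kwargs)
    Q = np.outer(ys, ys) * K
    n = len(y)

    def obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def jac(a):
        return -(np.ones(n) - Q @ a)

    res = minimize(
        obj, x0=np.full(n, min(C, 1.0) / 2), jac=jac, method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints={"type": "eq", "fun": lambda a: a @ ys, "jac": lambda a: ys},
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    a = res.x
    margin = (a > 1e-6 * C) & (a < C * (1 - 1e-6))
    if not margin.any():
        margin = a > 1e-6 * C
    f_no_b = (a * ys) @ K
    b = float(np.mean(ys[margin] - f_no_b[margin]))
    return f_no_b + b


class Kern:
    def __init__(self, metric, **kwargs):
        self.metric = metric
        self.kwargs = kwargs


class TestToyGeometry:
    def test_two_point_boundary_at_midpoint(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        svm = fit_svm(X, y, SVMConfig(kernel="linear", C=1000.0))
        labels, scores = predict(svm, X)
        np.testing.assert_array_equal(labels, y)
        assert svm.decision_function(np.array([[0.0]]))[0] == pytest.approx(0.0, abs=1e-6)

    def test_xor_rbf_separates_linear_cannot(self):
        rbf = fit_svm(XOR_X, XOR_Y, SVMConfig(kernel="rbf", C=10.0, gamma=1.0))
        labels, _ = predict(rbf, XOR_X)
        assert np.mean(labels == XOR_Y) == 1.0
        lin = fit_svm(XOR_X, XOR_Y, SVMConfig(kernel="linear", C=10.0))
        lin_labels, _ = predict(lin, XOR_X)
        assert np.mean(lin_labels == XOR_Y) <= 0.75

    def test_xor_linear_inseparability_is_structural(self):
        """LP feasibility: no affine separator exists for XOR (brute force)."""
        ys = np.where(XOR_Y == 1, 1.0, -1.0)
        # find w, b with y_i (w.x_i + b) >= 1: infeasible iff not separable
        A_ub = -(ys[:, None] * np.column_stack([XOR_X, np.ones(4)]))
        res = linprog(c=np.zeros(3), A_ub=A_ub, b_ub=-np.ones(4),
                      bounds=[(None, None)] * 3, method="highs")
        assert not res.success

    def test_regularization_strength(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.5, (20, 2)), rng.normal(2, 0.5, (20, 2))])
        y = np.repeat([0, 1], 20)
        hard = fit_svm(X, y, SVMConfig(kernel="rbf", C=1000.0, gamma=0.4))
        assert np.mean(predict(hard, X)[0] == y) == 1.0
        soft = fit_svm(X, y, SVMConfig(kernel="rbf", C=0.001, gamma=0.4))
        assert len(soft.support_vectors) > len(hard.support_vectors)

    def test_margin_violations_non_increasing_in_C(self):
        """Total hinge slack at the optimum shrinks as C grows; the 0-1
        training error follows the same trend across the ladder ends."""
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-1, 1.2, (40, 2)), rng.normal(1, 1.2, (40, 2))])
        y = np.repeat([0, 1], 40)
        ys = np.where(y == 1, 1.0, -1.0)
        slacks, errors = [], []
        for C in (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0):
            svm = fit_svm(X, y, SVMConfig(kernel="rbf", C=C, gamma=0.4))
            f = svm.decision_function(X)
            slacks.append(float(np.maximum(0.0, 1 - ys * f).sum()))
            errors.append(float(np.mean(predict(svm, X)[0] != y)))
        assert all(a >= b - 1e-9 for a, b in zip(slacks, slacks[1:]))
        assert errors[-1] <= errors[0]


class TestDualOracle:
    @pytest.mark.parametrize("kernel,config", [
        ("linear", SVMConfig(kernel="linear", C=1.0)),
        ("rbf", SVMConfig(kernel="rbf", C=1.0, gamma=0.4)),
        ("rbf", SVMConfig(kernel="rbf", C=10.0, gamma=1.0)),
    ])
    def test_decision_function_matches_brute_force(self, kernel, config):
        """Fitted decision values agree with a brute-force dual solve."""
        rng = np.random.default_rng(42)
        X = np.vstack([rng.normal(-1, 0.8, (8, 2)), rng.normal(1, 0.8, (8, 2))])
        y = np.repeat([0, 1], 8)
        svm = fit_svm(X, y, config)
        Xs = svm.scaler.transform(X)
        if kernel == "linear":
            oracle = brute_force_dual(Xs, y, config.C, Kern("linear"))
        else:
            oracle = brute_force_dual(Xs, y, config.C, Kern("rbf", gamma=config.gamma))
        ours = svm.decision_function(X)
        scale = max(1.0, np.abs(oracle).max())
        assert np.abs(ours - oracle).max() / scale < 5e-3

    def test_kernel_symmetry(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((12, 4))
        for metric, kw in [("linear", {}), ("rbf", {"gamma": 0.4}),
                           ("polynomial", {"degree": 3, "gamma": 0.4, "coef0": 0.0}),
                           ("sigmoid", {"gamma": 0.4, "coef0": 0.0})]:
            K = pairwise_kernels(X, metric=metric, **kw)
            np.testing.assert_allclose(K, K.T, atol=1e-12)


class TestPredict:
    def test_boundary_tie_goes_to_class_zero(self):
        class StubSVM:
            def decision_function(self, X):
                return np.array([0.0, -0.5, 0.5])

        labels, scores = predict(StubSVM(), np.zeros((3, 2)))
        np.testing.assert_array_equal(labels, [0, 0, 1])
        assert scores[0] == 0.0

    def test_standardization_folding_invariance(self):
        """Internal scaler vs externally standardized features: same output."""
        rng = np.random.default_rng(3)
        X = rng.normal(5.0, 3.0, (30, 4))
        y = (X[:, 0] + X[:, 1] > 8).astype(int)
        config = SVMConfig(kernel="rbf", C=1.0, gamma=0.4)
        internal = fit_svm(X, y, config)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Xs = (X - mu) / sd
        from sklearn.svm import SVC
        external = SVC(kernel="rbf", C=1.0, gamma=0.4).fit(Xs, y)
        np.testing.assert_allclose(internal.decision_function(X),
                                   external.decision_function(Xs), atol=1e-8)

    def test_errors(self):
        X = np.array([[0.0], [1.0]])
        with pytest.raises(ValueError):
            fit_svm(X, np.array([1, 1]), SVMConfig())
        with pytest.raises(ValueError):
            fit_svm(np.array([[np.nan], [1.0]]), np.array([0, 1]), SVMConfig())


class TestGridSearch:
    def test_tie_break_prefers_small_c_then_gamma(self):
        """On an easy separable set, many cells tie at 100%: the smallest
        (C, gamma) among the winners must be returned."""
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-4, 0.3, (20, 2)), rng.normal(4, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        best, table = grid_search(X, y, kernel="rbf", k=4, seed=0)
        means = table.mean(axis=1)
        winners = means[means == means.max()].index.tolist()
        assert (best.C, best.gamma, best.degree) == min(winners)

    def test_single_cell_grid(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 2))
        y = np.repeat([0, 1], 10)
        best, table = grid_search(X, y, kernel="rbf",
                                  grid={"C": [3.0], "gamma": [0.7]}, k=2)
        assert (best.C, best.gamma) == (3.0, 0.7)
        assert table.shape == (1, 2)

    def test_cv_table_shape(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        y = np.repeat([0, 1], 20)
        _, table = grid_search(X, y, kernel="rbf",
                               grid={"C": [0.1, 1.0], "gamma": [0.1, 0.4, 1.0]}, k=5)
        assert table.shape == (6, 5)

    def test_fold_count_exceeding_minority(self):
        X = np.random.default_rng(3).standard_normal((10, 2))
        y = np.array([0] * 8 + [1] * 2)
        with pytest.raises(ValueError):
            grid_search(X, y, kernel="rbf", k=5)
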