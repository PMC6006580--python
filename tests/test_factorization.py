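"""Objective, derivatives, Newton row updates and the alternating fit."""

import numpy as np
import pytest

import scmf
from scmf.factorization import (
    Hyperparameters,
    grad_x,
    grad_y,
    hessian_x,
    hessian_y,
    initialize,
    normalize_scores,
    objective,
    predict,
    resolve_k,
    update_x_row,
    update_y_row,
)

from _oracles import als_ridge, fd_gradient, fd_jacobian, objective_bruteforce
from conftest import random_instance


class TestResolveK:
    @pytest.mark.parametrize(
        "frac,n,m,expected",
        [
            (0.45, 269, 598, 121),
            (0.001, 100, 100, 1),  # rounds to 0, clipped up
            (0.5, 10, 20, 5),
            (1.0, 10, 10, 9),  # clipped below min(n, m)
        ],
    )
    def test_values(self, frac, n, m, expected):
        assert resolve_k(frac, n, m) == expected

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            resolve_k(0.0, 10, 10)


class TestInitialize:
    def test_deterministic_and_shapes(self):
        a = initialize(5, 7, 3, seed=42)
        b = initialize(5, 7, 3, seed=42)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.Y, b.Y)
        assert a.X.shape == (5, 3) and a.Y.shape == (7, 3)
        c = initialize(5, 7, 3, seed=43)
        assert not np.array_equal(a.X, c.X)
        assert a.X.min() > 0 and a.X.max() < 1 / np.sqrt(3)


class TestObjective:
    def test_zero_factors_closed_form(self):
        A = np.array([[1.0, 0.0], [1.0, 1.0]])
        X = np.zeros((2, 2))
        Y = np.zeros((2, 2))
        W = np.eye(2)
        assert objective(A, X, Y, W, W, mu=3.0, lam=7.0) == pytest.approx(0.5 * 3)

    def test_exact_factorization_zero(self, rng):
        X = rng.uniform(size=(4, 2))
        Y = rng.uniform(size=(3, 2))
        A = X @ Y.T
        assert objective(A, X, Y, np.eye(4), np.eye(3), 0.0 + 1e-300, 0.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        A, X, Y, Wd, Ws, mu, lam = random_instance(seed, n=4, m=3, k=2)
        expected = objective_bruteforce(A, X, Y, Wd, Ws, mu, lam)
        assert objective(A, X, Y, Wd, Ws, mu, lam) == pytest.approx(expected, abs=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            objective(np.ones((2, 2)), np.ones((2, 1)), np.ones((2, 1)),
                      np.eye(3), np.eye(2), 1.0, 1.0)


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_grad_x_matches_finite_differences(self, seed):
        A, X, Y, Wd, Ws, mu, lam = random_instance(seed)
        for i in range(A.shape[0]):
            def f(row, i=i):
                Xi = X.copy()
                Xi[i] = row
                return objective(A, Xi, Y, Wd, Ws, mu, lam)

            g = grad_x(i, A, X, Y, Wd, mu, lam)
            fd = fd_gradient(f, X[i])
            assert np.linalg.norm(g - fd) < 1e-5 * max(1.0, np.linalg.norm(fd))

    @pytest.mark.parametrize("seed", range(5))
    def test_grad_y_matches_finite_differences(self, seed):
        A, X, Y, Wd, Ws, mu, lam = random_instance(seed)
        for j in range(A.shape[1]):
            def f(row, j=j):
                Yj = Y.copy()
                Yj[j] = row
                return objective(A, X, Yj, Wd, Ws, mu, lam)

            g = grad_y(j, A, X, Y, Ws, mu, lam)
            fd = fd_gradient(f, Y[j])
            assert np.linalg.norm(g - fd) < 1e-5 * max(1.0, np.linalg.norm(fd))

    def test_lam_zero_reduction_and_ridge_stationarity(self, rng):
        A, X, Y, Wd, Ws, mu, _ = random_instance(11)
        i = 1
        g = grad_x(i, A, X, Y, Wd, mu, 0.0)
        expected = X[i] @ (Y.T @ Y + mu * np.eye(Y.shape[1])) - A[i] @ Y
        assert np.allclose(g, expected)
        # at the ridge solution the lam=0 gradient vanishes
        X[i] = A[i] @ Y @ np.linalg.inv(Y.T @ Y + mu * np.eye(Y.shape[1]))
        assert np.linalg.norm(grad_x(i, A, X, Y, Wd, mu, 0.0)) < 1e-10

    @pytest.mark.parametrize("seed", range(3))
    def test_hessians_match_fd_jacobian_of_gradient(self, seed):
        A, X, Y, Wd, Ws, mu, lam = random_instance(seed)
        i, j = 0, 1

        def gx(row):
            Xi = X.copy()
            Xi[i] = row
            return grad_x(i, A, Xi, Y, Wd, mu, lam)

        def gy(row):
            Yj = Y.copy()
            Yj[j] = row
            return grad_y(j, A, X, Yj, Ws, mu, lam)

        Hx = hessian_x(i, Y, Wd, mu, lam)
        Hy = hessian_y(j, X, Ws, mu, lam)
        assert np.abs(Hx - fd_jacobian(gx, X[i])).max() < 1e-5
        assert np.abs(Hy - fd_jacobian(gy, Y[j])).max() < 1e-5


class TestRowUpdates:
    @pytest.mark.parametrize("seed", range(5))
    def test_newton_exactness(self, seed):
        A, X, Y, Wd, Ws, mu, lam = random_instance(seed)
        for i in range(A.shape[0]):
            X[i] = update_x_row(i, A, X, Y, Wd, mu, lam)
            assert np.linalg.norm(grad_x(i, A, X, Y, Wd, mu, lam)) < 1e-8
        for j in range(A.shape[1]):
            Y[j] = update_y_row(j, A, X, Y, Ws, mu, lam)
            assert np.linalg.norm(grad_y(j, A, X, Y, Ws, mu, lam)) < 1e-8

    def test_lam_zero_is_ridge_closed_form(self):
        A, X, Y, Wd, Ws, mu, _ = random_instance(2)
        i = 2
        got = update_x_row(i, A, X, Y, Wd, mu, 0.0)
        ridge = A[i] @ Y @ np.linalg.inv(Y.T @ Y + mu * np.eye(Y.shape[1]))
        assert np.abs(got - ridge).max() < 1e-10

    def test_zero_similarity_equals_lam_zero(self):
        A, X, Y, _, _, mu, _ = random_instance(3)
        Wz = np.zeros((A.shape[0], A.shape[0]))
        assert np.allclose(
            update_x_row(0, A, X, Y, Wz, mu, 5.0),
            update_x_row(0, A, X, Y, Wz, mu, 0.0),
        )

    def test_verbatim_diagonal_shares_fixed_points(self):
        """The literal-diagonal update agrees once the row is stationary."""
        A, X, Y, Wd, Ws, mu, lam = random_instance(4, lam_scale=1.0)
        i = 0
        for _ in range(60):  # iterate the damped update to its fixed point
            X[i] = update_x_row(i, A, X, Y, Wd, mu, lam, verbatim_diagonal=True)
        exact = update_x_row(i, A, X, Y, Wd, mu, lam)
        assert np.allclose(X[i], exact, atol=1e-9)


class TestFit:
    def test_monotone_descent(self):
        for seed in range(5):
            A, _, _, Wd, Ws, mu, lam = random_instance(seed, n=10, m=8, k=3)
            hp = Hyperparameters(k=3, mu=mu, lam=lam, seed=seed, max_sweeps=30)
            r = scmf.fit(A, Wd, Ws, hp)
            diffs = np.diff(r.objective_trace)
            assert np.all(diffs <= 1e-9 * np.maximum(1.0, np.abs(r.objective_trace[:-1])))

    def test_rank_one_recovery(self, rng):
        u = (rng.uniform(size=12) < 0.6).astype(float)
        v = (rng.uniform(size=9) < 0.6).astype(float)
        A = np.outer(u, v)
        hp = Hyperparameters(k=1, mu=1e-4, lam=0.0, seed=0, max_sweeps=100)
        r = scmf.fit(A, np.eye(12), np.eye(9), hp)
        err = np.linalg.norm(A - predict(r.factors)) / np.linalg.norm(A)
        assert err < 0.05

    def test_tol_inf_runs_one_sweep(self):
        A, _, _, Wd, Ws, mu, lam = random_instance(0)
        hp = Hyperparameters(k=2, mu=mu, lam=lam, tol=np.inf)
        r = scmf.fit(A, Wd, Ws, hp)
        assert r.sweeps_run == 1 and r.converged

    def test_deterministic(self):
        A, _, _, Wd, Ws, mu, lam = random_instance(1)
        hp = Hyperparameters(k=2, mu=mu, lam=lam, seed=9, max_sweeps=20)
        r1 = scmf.fit(A, Wd, Ws, hp)
        r2 = scmf.fit(A, Wd, Ws, hp)
        assert np.array_equal(r1.factors.X, r2.factors.X)
        assert np.array_equal(r1.objective_trace, r2.objective_trace)

    def test_lam_zero_equals_plain_als(self):
        """With no similarity constraint the sweeps reduce to ridge ALS."""
        A, _, _, Wd, Ws, mu, _ = random_instance(5, n=8, m=6, k=2)
        k, sweeps = 2, 12
        init = initialize(8, 6, k, seed=3)
        hp = Hyperparameters(k=k, mu=mu, lam=0.0, seed=3, max_sweeps=sweeps, tol=0.0)
        r = scmf.fit(A, Wd, Ws, hp)
        Xo, Yo, trace = als_ridge(A, k, mu, sweeps, init.X, init.Y)
        assert np.abs(r.factors.X - Xo).max() < 1e-10
        assert np.abs(r.objective_trace[1:] - np.asarray(trace)).max() < 1e-10

    def test_asymmetric_similarity_rejected(self):
        A, _, _, Wd, Ws, mu, lam = random_instance(0)
        Wd = Wd.copy()
        Wd[0, 1] += 0.01
        with pytest.raises(ValueError, match="symmetric"):
            scmf.fit(A, Wd, Ws, Hyperparameters(k=2, mu=mu, lam=lam))


class TestPredictAndNormalize:
    def test_predict_matches_double_loop(self, rng):
        X = rng.normal(size=(4, 3))
        Y = rng.normal(size=(5, 3))
        P = predict(scmf.FactorPair(X, Y))
        assert P.shape == (4, 5)
        for i in range(4):
            for j in range(5):
                assert P[i, j] == pytest.approx(float(np.dot(X[i], Y[j])))

    def test_basis_rows_give_exact_one(self):
        X = np.eye(3)
        Y = np.eye(3)
        assert predict(scmf.FactorPair(X, Y))[1, 1] == 1.0

    def test_normalize(self):
        assert np.allclose(normalize_scores([2, 4, 6]), [0, 0.5, 1])
        s = np.array([3.0, -1.0, 7.0, 2.0])
        ns = normalize_scores(s)
        assert ns.min() == 0.0 and ns.max() == 1.0
        assert np.array_equal(np.argsort(ns), np.argsort(s))
        with pytest.warns(UserWarning, match="constant"):
            assert np.all(normalize_scores([5.0, 5.0]) == 0.0)
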