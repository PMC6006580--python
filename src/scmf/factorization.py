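"""Similarity-constrained matrix factorization of a drug-disease network.

The binary association matrix A (n drugs x m diseases) is approximated by
X Y^T with low-rank factors X (n x k) and Y (m x k), minimizing

    L = 1/2 sum_ij (a_ij - x_i y_j^T)^2
      + mu/2 (sum_i ||x_i||^2 + sum_j ||y_j||^2)
      + lam/2 sum_ij ||x_i - x_j||^2 w^d_ij
      + lam/2 sum_ij ||y_i - y_j||^2 w^s_ij

where w^d and w^s are drug-drug and disease-disease similarity matrices.
The similarity terms are graph-regularization penalties: entities similar in
feature space are forced to have nearby latent embeddings.

L is quadratic in each factor row with the others fixed, so a Newton step on
a row lands exactly at its minimizer.  Optimization alternates Gauss-Seidel
sweeps over all drug rows then all disease rows, each row solved by a k x k
linear system; every update exactly minimizes the objective in that row, so
the per-sweep objective trace is non-increasing.

Note on the similarity self-terms: the j = i summand of the penalty,
||x_i - x_i||^2 w_ii, is identically zero, so w_ii appears in neither the
gradient nor the true curvature of L.  The default row update therefore
excludes the diagonal from the similarity sums, which makes the update the
exact row minimizer.  ``verbatim_diagonal=True`` instead keeps w_ii in both
the scalar damping and the right-hand side (evaluated at the current row) —
a majorize-minimize step with the same fixed points, still monotone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import as_array

__all__ = [
    "Hyperparameters",
    "FactorPair",
    "FitResult",
    "resolve_k",
    "initialize",
    "objective",
    "grad_x",
    "grad_y",
    "hessian_x",
    "hessian_y",
    "update_x_row",
    "update_y_row",
    "fit",
    "predict",
    "normalize_scores",
]


def resolve_k(k_fraction: float, n: int, m: int) -> int:
    """Resolve a latent dimension given as a fraction of k0 = min(n, m).

    Rounds half away from zero and clips into [1, min(n, m) - 1].
    """
    if not 0.0 < k_fraction <= 1.0:
        raise ValueError(f"k_fraction must be in (0, 1], got {k_fraction}")
    k0 = min(n, m)
    k = int(math.floor(k_fraction * k0 + 0.5))
    return max(1, min(k, k0 - 1))


@dataclass
class Hyperparameters:
    """Model hyperparameters.

    ``k`` may be given directly or as ``k_fraction`` of min(n, m); ``mu`` is
    the L2 weight and ``lam`` the similarity-constraint weight.  Defaults
    mu=1 (2^0), lam=4 (2^2), k_fraction=0.45 are the grid-search optimum for
    this model family on dense curated association data.
    """

    k: int | None = None
    k_fraction: float | None = 0.45
    mu: float = 1.0
    lam: float = 4.0
    max_sweeps: int = 200
    tol: float = 1e-6
    seed: int = 0
    verbatim_diagonal: bool = False

    def resolve(self, n: int, m: int) -> int:
        if self.k is not None:
            if not 1 <= self.k < min(n, m):
                raise ValueError(
                    f"k={self.k} outside [1, {min(n, m) - 1}] for a {n}x{m} matrix"
                )
            return int(self.k)
        if self.k_fraction is None:
            raise ValueError("one of k or k_fraction must be set")
        return resolve_k(self.k_fraction, n, m)

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive (the row systems need mu > 0)")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


@dataclass
class FactorPair:
    """Latent factors: drug rows X (n x k) and disease rows Y (m x k)."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2 or self.X.shape[1] != self.Y.shape[1]:
            raise ValueError(
                f"factor shapes incompatible: {self.X.shape} vs {self.Y.shape}"
            )


@dataclass
class FitResult:
    factors: FactorPair
    objective_trace: np.ndarray  # objective before any sweep, then per sweep
    sweeps_run: int
    converged: bool


def initialize(n: int, m: int, k: int, seed: int) -> FactorPair:
    """Random initial factors: i.i.d. Uniform(0, 1) / sqrt(k).

    The 1/sqrt(k) scaling keeps initial inner products x_i y_j^T of order
    one regardless of the latent dimension.
    """
    rng = np.random.default_rng(seed)
    scale = 1.0 / math.sqrt(k)
    return FactorPair(
        X=rng.uniform(0.0, 1.0, size=(n, k)) * scale,
        Y=rng.uniform(0.0, 1.0, size=(m, k)) * scale,
    )


def _pair_weights(W: np.ndarray, include_diag: bool) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrized pair weights t = W + W^T and their row sums.

    With ``include_diag=False`` the diagonal is zeroed: the self-terms of
    the penalty vanish identically, so excluding them yields the exact
    gradient/curvature.
    """
    t = W + W.T
    if not include_diag:
        t = t.copy()
        np.fill_diagonal(t, 0.0)
    return t, t.sum(axis=1)


def objective(A, X, Y, Wd, Ws, mu: float, lam: float) -> float:
    """Evaluate the full objective L (reconstruction + L2 + graph penalties)."""
    A, X, Y = as_array(A), np.asarray(X, float), np.asarray(Y, float)
    Wd, Ws = as_array(Wd), as_array(Ws)
    n, m = A.shape
    if X.shape[0] != n or Y.shape[0] != m or Wd.shape != (n, n) or Ws.shape != (m, m):
        raise ValueError("shape mismatch between A, X, Y, Wd, Ws")
    R = A - X @ Y.T
    L = 0.5 * float(np.sum(R * R))
    L += 0.5 * mu * (float(np.sum(X * X)) + float(np.sum(Y * Y)))

    def smooth(F: np.ndarray, W: np.ndarray) -> float:
        sq = np.einsum("ij,ij->i", F, F)
        cross = float(np.trace(F.T @ (W @ F)))
        return 0.5 * (float(sq @ W.sum(axis=1)) + float(sq @ W.sum(axis=0)) - 2.0 * cross)

    if lam != 0.0:
        L += lam * (smooth(X, Wd) + smooth(Y, Ws))
    return L


def grad_x(i: int, A, X, Y, Wd, mu: float, lam: float) -> np.ndarray:
    """Gradient of L with respect to drug row x_i (a k-vector).

    Equals x_i (Y^T Y + mu I + lam s_i I) - A(i,:) Y - lam sum_j (w_ij + w_ji) x_j;
    the j = i contributions cancel identically, so the value is independent
    of w_ii.
    """
    A, X, Y, Wd = as_array(A), np.asarray(X, float), np.asarray(Y, float), as_array(Wd)
    t, s = _pair_weights(Wd, include_diag=False)
    return (
        X[i] @ (Y.T @ Y)
        + (mu + lam * s[i]) * X[i]
        - A[i] @ Y
        - lam * (t[i] @ X)
    )


def grad_y(j: int, A, X, Y, Ws, mu: float, lam: float) -> np.ndarray:
    """Gradient of L with respect to disease row y_j (mirror of grad_x)."""
    A, X, Y, Ws = as_array(A), np.asarray(X, float), np.asarray(Y, float), as_array(Ws)
    t, s = _pair_weights(Ws, include_diag=False)
    return (
        Y[j] @ (X.T @ X)
        + (mu + lam * s[j]) * Y[j]
        - A[:, j] @ X
        - lam * (t[j] @ Y)
    )


def hessian_x(i: int, Y, Wd, mu: float, lam: float, include_diag: bool = False) -> np.ndarray:
    """Row Hessian Y^T Y + (mu + lam s_i) I.

    The default excludes w_ii from s_i, matching the true curvature of L;
    ``include_diag=True`` gives the inflated scalar of the literal printed
    sums (see module docstring).
    """
    Y, Wd = np.asarray(Y, float), as_array(Wd)
    _, s = _pair_weights(Wd, include_diag)
    k = Y.shape[1]
    return Y.T @ Y + (mu + lam * s[i]) * np.eye(k)


def hessian_y(j: int, X, Ws, mu: float, lam: float, include_diag: bool = False) -> np.ndarray:
    """Row Hessian X^T X + (mu + lam s_j) I (mirror of hessian_x)."""
    X, Ws = np.asarray(X, float), as_array(Ws)
    _, s = _pair_weights(Ws, include_diag)
    k = X.shape[1]
    return X.T @ X + (mu + lam * s[j]) * np.eye(k)


def _solve_row(H: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(H, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular row system: the updates require mu > 0"
        ) from exc


def update_x_row(
    i: int, A, X, Y, Wd, mu: float, lam: float, verbatim_diagonal: bool = False
) -> np.ndarray:
    """Newton update of drug row x_i; exact row minimizer by default."""
    A, X, Y, Wd = as_array(A), np.asarray(X, float), np.asarray(Y, float), as_array(Wd)
    t, s = _pair_weights(Wd, include_diag=verbatim_diagonal)
    H = Y.T @ Y + (mu + lam * s[i]) * np.eye(Y.shape[1])
    rhs = A[i] @ Y + lam * (t[i] @ X)
    return _solve_row(H, rhs)


def update_y_row(
    j: int, A, X, Y, Ws, mu: float, lam: float, verbatim_diagonal: bool = False
) -> np.ndarray:
    """Newton update of disease row y_j; exact row minimizer by default."""
    A, X, Y, Ws = as_array(A), np.asarray(X, float), np.asarray(Y, float), as_array(Ws)
    t, s = _pair_weights(Ws, include_diag=verbatim_diagonal)
    H = X.T @ X + (mu + lam * s[j]) * np.eye(X.shape[1])
    rhs = A[:, j] @ X + lam * (t[j] @ Y)
    return _solve_row(H, rhs)


def fit(
    A,
    Wd,
    Ws,
    hp: Hyperparameters | None = None,
    initial: FactorPair | None = None,
    callback=None,
) -> FitResult:
    """Alternating Newton row updates until the objective stabilizes.

    Each sweep updates all drug rows in order, then all disease rows, using
    freshly updated rows within the sweep (Gauss-Seidel).  Convergence:
    relative objective change below ``hp.tol`` (|L_t - L_{t-1}| /
    max(1, L_{t-1})) or ``hp.max_sweeps`` reached.
    """
    hp = hp or Hyperparameters()
    A = as_array(A)
    Wd = as_array(Wd)
    Ws = as_array(Ws)
    n, m = A.shape
    if Wd.shape != (n, n) or Ws.shape != (m, m):
        raise ValueError(
            f"similarity shapes {Wd.shape}/{Ws.shape} do not match A {A.shape}"
        )
    for W, name in ((Wd, "drug"), (Ws, "disease")):
        if np.abs(W - W.T).max() > 1e-8:
            raise ValueError(f"{name} similarity matrix is not symmetric (tol 1e-8)")

    k = hp.resolve(n, m)
    if initial is None:
        factors = initialize(n, m, k, hp.seed)
    else:
        factors = FactorPair(initial.X.copy(), initial.Y.copy())
        if factors.X.shape != (n, k) or factors.Y.shape != (m, k):
            raise ValueError("initial factors have wrong shape")
    X, Y = factors.X, factors.Y

    mu, lam = hp.mu, hp.lam
    td, sd = _pair_weights(Wd, include_diag=hp.verbatim_diagonal)
    ts, ss = _pair_weights(Ws, include_diag=hp.verbatim_diagonal)
    eye_k = np.eye(k)

    trace = [objective(A, X, Y, Wd, Ws, mu, lam)]
    converged = False
    sweeps = 0
    for sweep in range(hp.max_sweeps):
        G = Y.T @ Y
        AY = A @ Y
        for i in range(n):
            rhs = AY[i] + lam * (td[i] @ X)
            X[i] = _solve_row(G + (mu + lam * sd[i]) * eye_k, rhs)
        G = X.T @ X
        AX = A.T @ X
        for j in range(m):
            rhs = AX[j] + lam * (ts[j] @ Y)
            Y[j] = _solve_row(G + (mu + lam * ss[j]) * eye_k, rhs)
        L = objective(A, X, Y, Wd, Ws, mu, lam)
        if not np.isfinite(L):
            raise RuntimeError(f"objective diverged to {L} at sweep {sweep + 1}")
        trace.append(L)
        sweeps = sweep + 1
        if callback is not None:
            callback(sweeps, L)
        if abs(trace[-2] - L) / max(1.0, abs(trace[-2])) < hp.tol:
            converged = True
            break
    return FitResult(
        factors=FactorPair(X, Y),
        objective_trace=np.asarray(trace),
        sweeps_run=sweeps,
        converged=converged,
    )


def predict(factors: FactorPair) -> np.ndarray:
    """Prediction score matrix X Y^T.

    Entries rank candidate drug-disease pairs; they are inner products of
    latent rows and are not clipped to [0, 1].
    """
    return factors.X @ factors.Y.T


def normalize_scores(scores) -> np.ndarray:
    """Min-max rescale scores to [0, 1]: (score - min) / (max - min).

    A monotone transform for reporting only; constant input maps to zeros
    with a warning.
    """
    import warnings

    s = np.asarray(scores, dtype=float)
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        warnings.warn("constant scores: min-max normalization returns all zeros")
        return np.zeros_like(s)
    return (s - lo) / (hi - lo)
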