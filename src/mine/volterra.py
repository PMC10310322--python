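"""Direct Volterra-kernel regression and effective-degrees-of-freedom analysis.

A second-order discrete Volterra model with memory ``T`` lags predicts

    r(t) = k0 + sum_i k1(i) s(t-i) + sum_{i,j} k2(i,j) s(t-i) s(t-j)

and can be fit by ordinary least squares or ridge regression on a polynomial
design matrix.  The design uses unique products ``i <= j`` (mathematically
identical to the full double sum, better conditioned); off-diagonal
coefficients are halved when unpacked into the symmetric ``k2``.

Model flexibility is compared through effective degrees of freedom: the
analytic hat-matrix trace for ridge models, and a covariance-based simulation
estimate for arbitrary estimators such as the encoder network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VolterraDesign",
    "KernelEstimate",
    "build_design",
    "fit_volterra",
    "ridge_edf",
    "simulation_edf",
]


@dataclass
class VolterraDesign:
    """Quadratic polynomial design over lagged copies of one stimulus.

    Columns: ``[1, s(t), .., s(t-T), s(t-i)s(t-j) for i <= j]`` in
    lexicographic (i, j) order; row ``k`` corresponds to time ``T + k``.
    """

    X: np.ndarray
    memory: int  # T: lags 0..T, i.e. T+1 taps
    t_index: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def rank_deficient(self) -> bool:
        return np.linalg.matrix_rank(self.X) < self.X.shape[1]


def build_design(stimulus: np.ndarray, memory: int = 49) -> VolterraDesign:
    """Design matrix for a second-order Volterra fit with ``memory + 1`` taps."""
    s = np.asarray(stimulus, float).ravel()
    T = int(memory)
    if s.shape[0] <= T:
        raise ValueError(f"stimulus length {s.shape[0]} must exceed memory {T}")
    n_rows = s.shape[0] - T
    # lag matrix L[k, i] = s(T + k - i), i = 0..T
    L = np.empty((n_rows, T + 1))
    for i in range(T + 1):
        L[:, i] = s[T - i : s.shape[0] - i]
    iu, ju = np.triu_indices(T + 1)
    prods = L[:, iu] * L[:, ju]
    X = np.hstack([np.ones((n_rows, 1)), L, prods])
    return VolterraDesign(X=X, memory=T, t_index=np.arange(T, s.shape[0]))


@dataclass
class KernelEstimate:
    """Unpacked Volterra kernels (k2 symmetric)."""

    k0: float
    k1: np.ndarray
    k2: np.ndarray
    method: str = "ols"

    def predict(self, design: VolterraDesign) -> np.ndarray:
        """Model response on the rows of a (compatible) design matrix."""
        return design.X @ self._beta()

    def _beta(self) -> np.ndarray:
        T1 = self.k1.shape[0]
        iu, ju = np.triu_indices(T1)
        coefs = np.where(iu == ju, 1.0, 2.0) * self.k2[iu, ju]
        return np.concatenate([[self.k0], self.k1, coefs])


def fit_volterra(
    design: VolterraDesign,
    response: np.ndarray,
    method: str = "ols",
    alpha: float = 0.0,
) -> KernelEstimate:
    """Estimate (k0, k1, k2) by OLS or ridge regression.

    Under-determined OLS falls back to the minimum-norm solution with a
    warning.  Ridge solves ``(X^T X + alpha I) beta = X^T y`` (the intercept
    column is penalized along with everything else, matching a plain ridge
    on the full polynomial design).
    """
    X = design.X
    y = np.asarray(response, float).ravel()
    if y.shape[0] != X.shape[0]:
        raise ValueError(f"response length {y.shape[0]} != design rows {X.shape[0]}")
    if method == "ols":
        if X.shape[0] < X.shape[1] or design.rank_deficient:
            warnings.warn(
                "OLS design is singular/under-determined; using the "
                "minimum-norm solution",
                UserWarning,
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    elif method == "ridge":
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        A = X.T @ X + alpha * np.eye(X.shape[1])
        beta = np.linalg.solve(A, X.T @ y)
    else:
        raise ValueError(f"unknown method {method!r}")
    T1 = design.memory + 1
    k0 = float(beta[0])
    k1 = beta[1 : 1 + T1].copy()
    k2 = np.zeros((T1, T1))
    iu, ju = np.triu_indices(T1)
    coefs = beta[1 + T1 :]
    k2[iu, ju] = np.where(iu == ju, coefs, coefs / 2.0)
    k2 = k2 + np.triu(k2, 1).T
    label = method if method == "ols" else f"ridge(alpha={alpha:g})"
    return KernelEstimate(k0=k0, k1=k1, k2=k2, method=label)


def ridge_edf(design: VolterraDesign | np.ndarray, alpha: float) -> float:
    """Effective degrees of freedom of a ridge fit: trace of the hat matrix.

    Computed through the eigenvalues of ``X^T X`` as ``sum lambda_i /
    (lambda_i + alpha)`` — stable, and exact for ``alpha = 0`` (the column
    rank).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    X = design.X if isinstance(design, VolterraDesign) else np.asarray(design, float)
    lam = np.linalg.eigvalsh(X.T @ X)
    lam = np.clip(lam, 0.0, None)
    if alpha == 0:
        tol = lam.max() * max(X.shape) * np.finfo(float).eps if lam.size else 0.0
        return float((lam > tol).sum())
    return float(np.sum(lam / (lam + alpha)))


def simulation_edf(
    fit_predict,
    signal: np.ndarray,
    noise_sd: float,
    n_reps: int = 20,
    seed: int | np.random.Generator = 0,
) -> float:
    """Covariance-based effective degrees of freedom of an arbitrary estimator.

    Repeatedly redraws i.i.d. Gaussian output noise around a fixed signal,
    refits the estimator via ``fit_predict(y, rep_seed) -> yhat`` and
    computes ``df = sum_i Cov(yhat_i, y_i) / sigma^2`` across replicates.
    An interpolating estimator returns the sample count; a constant one 0.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    signal = np.asarray(signal, float).ravel()
    rng = np.random.default_rng(seed)
    N = signal.shape[0]
    ys = np.empty((n_reps, N))
    yhats = np.empty((n_reps, N))
    for r in range(n_reps):
        y = signal + noise_sd * rng.standard_normal(N)
        ys[r] = y
        yhats[r] = np.asarray(fit_predict(y, int(rng.integers(2 ** 31)))).ravel()
    yc = ys - ys.mean(axis=0)
    hc = yhats - yhats.mean(axis=0)
    cov = (yc * hc).sum(axis=0) / (n_reps - 1)
    return float(cov.sum() / noise_sd ** 2)
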