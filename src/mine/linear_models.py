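"""Linear-regression comparison models.

Three baselines of increasing sophistication, all sharing the encoder's
temporal train/test split so their test correlations are directly comparable
to the network's:

* ``simple_lm`` — OLS on the raw predictor traces.  Cannot represent
  indicator dynamics or temporal shifts.
* ``expanded_lm`` — OLS on calcium-kernel-convolved (optionally transformed)
  predictors plus all pairwise interaction products; the classic
  design-with-prior-knowledge model.
* ``shifted_ridge_lm`` — ridge regression on time-shifted copies of every
  predictor (default 50 shifts), orthogonalized by modified Gram-Schmidt;
  the strongest generic linear competitor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .encoder import pearson_r

__all__ = [
    "LMResult",
    "simple_lm",
    "expanded_lm",
    "shifted_ridge_lm",
    "modified_gram_schmidt",
    "build_shifted_design",
]


@dataclass
class LMResult:
    """Train/test Pearson correlations and coefficients of a linear fit."""

    train_corr: float
    test_corr: float
    coefs: np.ndarray
    intercept: float


def _temporal_split(n: int, train_fraction: float) -> int:
    n_train = int(round(n * train_fraction))
    return min(max(n_train, 1), n - 1)


def _ols_fit(X: np.ndarray, y: np.ndarray, train_fraction: float, alpha: float = 0.0) -> LMResult:
    n_train = _temporal_split(X.shape[0], train_fraction)
    Xtr = np.column_stack([np.ones(n_train), X[:n_train]])
    if alpha > 0:
        A = Xtr.T @ Xtr + alpha * np.eye(Xtr.shape[1])
        beta = np.linalg.solve(A, Xtr.T @ y[:n_train])
    else:
        if np.linalg.matrix_rank(Xtr) < Xtr.shape[1]:
            warnings.warn("rank-deficient design; using minimum-norm solution", UserWarning)
        beta, *_ = np.linalg.lstsq(Xtr, y[:n_train], rcond=None)
    yhat = np.column_stack([np.ones(X.shape[0]), X]) @ beta
    return LMResult(
        train_corr=pearson_r(yhat[:n_train], y[:n_train]),
        test_corr=pearson_r(yhat[n_train:], y[n_train:]),
        coefs=beta[1:],
        intercept=float(beta[0]),
    )


def simple_lm(
    predictors: np.ndarray,
    response: np.ndarray,
    train_fraction: float = 2.0 / 3.0,
) -> LMResult:
    """OLS of the response on the raw predictor traces (P, T)."""
    X = np.atleast_2d(np.asarray(predictors, float)).T
    y = np.asarray(response, float).ravel()
    return _ols_fit(X, y, train_fraction)


def expanded_lm(
    predictors: np.ndarray,
    response: np.ndarray,
    ca_kernel: np.ndarray,
    transforms: Sequence[Callable[[np.ndarray], np.ndarray]] | None = None,
    train_fraction: float = 2.0 / 3.0,
) -> LMResult:
    """Calcium-convolved linear model with first-order interactions.

    Each (optionally pre-transformed) predictor is convolved with the known
    calcium kernel; the design contains these traces plus all pairwise
    products between them (products formed after convolution).  Supplying
    ``transforms`` encodes a-posteriori knowledge of the response
    nonlinearity, as in the classic designed-regression approach.
    """
    values = np.atleast_2d(np.asarray(predictors, float))
    y = np.asarray(response, float).ravel()
    ca_kernel = np.asarray(ca_kernel, float)
    if transforms is not None:
        if len(transforms) != values.shape[0]:
            raise ValueError("one transform per predictor required")
        values = np.vstack([f(v) for f, v in zip(transforms, values)])
    conv = np.vstack(
        [np.convolve(v, ca_kernel, mode="full")[: values.shape[1]] for v in values]
    )
    cols = [conv[p] for p in range(conv.shape[0])]
    for i in range(conv.shape[0]):
        for j in range(i + 1, conv.shape[0]):
            cols.append(conv[i] * conv[j])
    return _ols_fit(np.column_stack(cols), y, train_fraction)


def build_shifted_design(predictors: np.ndarray, n_shifts: int = 50) -> np.ndarray:
    """Columns = each predictor delayed by 0 .. n_shifts-1 samples.

    Shifted-in values at the start of a column are zero-padded.  With the
    default 50 shifts, P predictors yield ``50 P`` columns, emulating the
    encoder's 50-sample temporal filters.
    """
    values = np.atleast_2d(np.asarray(predictors, float))
    P, T = values.shape
    cols = np.empty((T, P * n_shifts))
    c = 0
    for p in range(P):
        for k in range(n_shifts):
            col = np.zeros(T)
            col[k:] = values[p, : T - k]
            cols[:, c] = col
            c += 1
    return cols


def modified_gram_schmidt(
    matrix: np.ndarray,
    drop_tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormalize columns with the modified Gram-Schmidt process.

    Numerically stabler than classical Gram-Schmidt/QR on near-singular
    designs.  Columns whose residual norm falls below ``drop_tol`` times
    their original norm are linearly dependent on earlier ones; they are
    dropped and reported.  Returns ``(Q, kept_indices)``.
    """
    A = np.array(matrix, float, copy=True)
    n_cols = A.shape[1]
    kept: list[int] = []
    qs: list[np.ndarray] = []
    orig_norms = np.linalg.norm(A, axis=0)
    for j in range(n_cols):
        v = A[:, j]
        for q in qs:
            v = v - (q @ v) * q
        nrm = np.linalg.norm(v)
        ref = orig_norms[j] if orig_norms[j] > 0 else 1.0
        if nrm <= drop_tol * ref or nrm == 0.0:
            continue  # dependent column: flag by omission
        qs.append(v / nrm)
        kept.append(j)
    Q = np.column_stack(qs) if qs else np.empty((A.shape[0], 0))
    return Q, np.asarray(kept, dtype=int)


def shifted_ridge_lm(
    predictors: np.ndarray,
    response: np.ndarray,
    n_shifts: int = 50,
    alpha: float = 1e-4,
    train_fraction: float = 2.0 / 3.0,
    orthogonalize: bool = True,
) -> LMResult:
    """Ridge regression on the orthogonalized time-shifted design.

    The small default penalty (1e-4) mainly guards against the near-singular
    directions that survive orthogonalization at floating-point precision.
    """
    y = np.asarray(response, float).ravel()
    X = build_shifted_design(predictors, n_shifts)
    if orthogonalize:
        X, _ = modified_gram_schmidt(X)
    return _ols_fit(X, y, train_fraction, alpha=alpha)
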