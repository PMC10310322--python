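"""Taylor-expansion characterization of a fitted encoder.

All operations work on any "differentiable model": an object exposing
``predict(X) -> (n,)`` for batches of flattened windows, ``taylor_state(x) ->
(f, J, H)`` for the value/gradient/Hessian at a single window, and optionally
a batched ``input_gradient(X) -> (n, D)``.  The trained encoder implements
this protocol; tests exercise the same code paths with hand-differentiable
polynomial models.

Two complementary analyses:

* Global complexity: one expansion at the data mean.  The variance of the
  true network output explained by the first-order truncation (LAS) and by
  the second-order truncation (SOS) classifies the neuron as linear
  (LAS >= 0.8), second-order (LAS < 0.8, SOS >= 0.5) or complex (otherwise).
* Local predictor attribution: expansions every few samples, predicting the
  *change* in output some lookahead into the future.  Removing a predictor's
  (or an interaction's) terms from every local expansion and measuring the
  lost variance-explained yields the Taylor metric, with bootstrap standard
  errors over expansion points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .data import WindowTensor, predictor_index_blocks
from .encoder import pearson_r
from .errors import UndefinedScoreError

__all__ = [
    "ExpansionState",
    "ComplexityScores",
    "TaylorReport",
    "derivatives_at",
    "approximation_scores",
    "complexity_class",
    "taylor_metric",
    "bootstrap_taylor",
    "curvature_metric",
    "nlc",
]

LAS_THRESHOLD = 0.8  # linear-approximation score below this flags nonlinearity
SOS_THRESHOLD = 0.5  # second-order score below this flags high complexity


@dataclass
class ExpansionState:
    """Network value, gradient and (symmetrized) Hessian at one input."""

    x: np.ndarray
    f: float
    J: np.ndarray
    H: np.ndarray


def derivatives_at(model, x: np.ndarray) -> ExpansionState:
    """Exact value/gradient/Hessian of the model output at input ``x``.

    The Hessian is symmetrized as ``(H + H^T) / 2``; non-finite derivatives
    raise immediately rather than propagating NaNs into downstream metrics.
    """
    x = np.asarray(x, float).ravel()
    f, J, H = model.taylor_state(x)
    H = 0.5 * (H + H.T)
    if not (np.isfinite(f) and np.all(np.isfinite(J)) and np.all(np.isfinite(H))):
        raise FloatingPointError("non-finite derivatives at expansion point")
    return ExpansionState(x=x, f=float(f), J=J, H=H)


def _batch_gradient(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "input_gradient"):
        return model.input_gradient(X)
    return np.vstack([derivatives_at(model, x).J for x in X])


# ----------------------------------------------------------------- complexity
@dataclass
class ComplexityScores:
    """Variance of the network output explained by Taylor truncations."""

    las: float
    sos: float

    @property
    def complexity_class(self) -> int:
        return complexity_class(self)


def approximation_scores(
    model,
    windows: WindowTensor | np.ndarray,
    stride: int = 5,
    x_bar: np.ndarray | None = None,
) -> ComplexityScores:
    """Linear and second-order approximation scores around the data mean.

    Expands the model at ``x_bar`` (default: mean of the supplied windows) and
    scores each truncation's predictions against the true model output on
    windows sampled every ``stride`` samples (default 5 = 1 s at 5 Hz):
    ``LAS = 1 - mean((f - f_1st)^2) / var(f)``, analogously for SOS.
    """
    X = windows.flat if isinstance(windows, WindowTensor) else np.atleast_2d(windows)
    if x_bar is None:
        x_bar = X.mean(axis=0)
    samples = X[::stride]
    state = derivatives_at(model, x_bar)
    f_true = np.asarray(model.predict(samples), float).ravel()
    var_f = f_true.var()
    if var_f < 1e-12:
        raise UndefinedScoreError("model output variance vanishes on the data")
    d = samples - state.x
    lin = state.f + d @ state.J
    quad = lin + 0.5 * np.einsum("ij,jk,ik->i", d, state.H, d)
    las = 1.0 - float(np.mean((f_true - lin) ** 2)) / var_f
    sos = 1.0 - float(np.mean((f_true - quad) ** 2)) / var_f
    return ComplexityScores(las=las, sos=sos)


def complexity_class(scores: ComplexityScores) -> int:
    """0 = linear, 1 = second order suffices, 2 = higher order needed."""
    if scores.las >= LAS_THRESHOLD:
        return 0
    if scores.sos >= SOS_THRESHOLD:
        return 1
    return 2


# --------------------------------------------------------------- Taylor metric
@dataclass
class TaylorReport:
    """Per-predictor / per-interaction Taylor metrics with bootstrap errors.

    ``t_pred[n] = 1 - r2(-n) / r2_full`` measures the fraction of explained
    variance of predicted output *changes* lost when predictor ``n``'s linear
    and quadratic terms are removed; ``t_inter`` does the same for the pure
    interaction terms of each predictor pair.  ``usable`` is False when the
    full expansion itself explains (essentially) nothing.
    """

    predictor_names: list[str]
    pair_names: list[tuple[str, str]]
    r2_full: float
    t_pred: np.ndarray
    t_inter: np.ndarray
    se_pred: np.ndarray | None = None
    se_inter: np.ndarray | None = None
    sig_pred: np.ndarray | None = None
    sig_inter: np.ndarray | None = None
    usable: bool = True
    # raw per-expansion-point terms, kept for bootstrapping
    delta_true: np.ndarray = field(default=None, repr=False)
    delta_full: np.ndarray = field(default=None, repr=False)
    contrib_pred: np.ndarray = field(default=None, repr=False)
    contrib_inter: np.ndarray = field(default=None, repr=False)

    @property
    def n_expansions(self) -> int:
        return 0 if self.delta_true is None else self.delta_true.shape[0]


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    return pearson_r(a, b) ** 2


def taylor_metric(
    model,
    windows: WindowTensor,
    predictor_names: list[str] | None = None,
    look_ahead: int = 25,
    stride: int = 5,
    min_points: int = 50,
) -> TaylorReport:
    """Attribute output changes to predictors via local 2nd-order expansions.

    At every ``stride``-th window ``x = X(t)`` the model is expanded and the
    change in output to ``x' = X(t + look_ahead)`` is predicted.  Changes
    (rather than raw outputs) are compared so that the metric reflects what
    *drives* the output, not what sets its baseline.  Contributions of each
    predictor (gradient + own-quadratic terms) and of each predictor pair
    (cross terms only) are accumulated so they can be removed and re-scored.
    """
    h, P = windows.history_n, windows.n_predictors
    if predictor_names is None:
        predictor_names = [f"P{i}" for i in range(P)]
    X = windows.flat
    n_points = (X.shape[0] - look_ahead - 1) // stride + 1 if X.shape[0] > look_ahead else 0
    if n_points < min_points:
        raise ValueError(
            f"only {n_points} expansion points (need >= {min_points}); "
            "provide more data or reduce stride/look_ahead"
        )
    idx0 = np.arange(n_points) * stride
    blocks = predictor_index_blocks(h, P)
    pairs = [(i, j) for i in range(P) for j in range(i + 1, P)]

    f_now = np.asarray(model.predict(X[idx0]), float).ravel()
    f_next = np.asarray(model.predict(X[idx0 + look_ahead]), float).ravel()
    delta_true = f_next - f_now

    delta_full = np.empty(n_points)
    contrib_pred = np.empty((P, n_points))
    contrib_inter = np.empty((len(pairs), n_points))
    for k, i0 in enumerate(idx0):
        state = derivatives_at(model, X[i0])
        d = X[i0 + look_ahead] - state.x
        Hd = state.H @ d
        delta_full[k] = d @ state.J + 0.5 * d @ Hd
        for n, bn in enumerate(blocks):
            dn = d[bn]
            contrib_pred[n, k] = dn @ state.J[bn] + 0.5 * dn @ state.H[np.ix_(bn, bn)] @ dn
        for q, (i, j) in enumerate(pairs):
            di, dj = d[blocks[i]], d[blocks[j]]
            contrib_inter[q, k] = di @ state.H[np.ix_(blocks[i], blocks[j])] @ dj

    r2_full = _r2(delta_true, delta_full)
    usable = r2_full > 1e-6
    t_pred = np.zeros(P)
    t_inter = np.zeros(len(pairs))
    if usable:
        for n in range(P):
            t_pred[n] = 1.0 - _r2(delta_true, delta_full - contrib_pred[n]) / r2_full
        for q in range(len(pairs)):
            t_inter[q] = 1.0 - _r2(delta_true, delta_full - contrib_inter[q]) / r2_full
    return TaylorReport(
        predictor_names=list(predictor_names),
        pair_names=[(predictor_names[i], predictor_names[j]) for i, j in pairs],
        r2_full=r2_full,
        t_pred=t_pred,
        t_inter=t_inter,
        usable=usable,
        delta_true=delta_true,
        delta_full=delta_full,
        contrib_pred=contrib_pred,
        contrib_inter=contrib_inter,
    )


def _boot_r2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rowwise squared Pearson correlation for (n_boot, K) resampled arrays."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).mean(axis=1)
    den = ac.std(axis=1) * bc.std(axis=1)
    out = np.zeros(a.shape[0])
    ok = den > 0
    out[ok] = (num[ok] / den[ok]) ** 2
    return out


def bootstrap_taylor(
    report: TaylorReport,
    n_boot: int = 1000,
    threshold: float = 0.1,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    seed: int | np.random.Generator = 0,
) -> TaylorReport:
    """Bootstrap SEs and significance flags for the Taylor metrics.

    Expansion points are resampled with replacement; the SD of the bootstrap
    variates estimates the SE, and a predictor is flagged significant when its
    metric exceeds ``threshold`` by ``z * SE`` with ``z`` from the (Bonferroni
    corrected over ``n_comparisons``) one-sided normal quantile.  Mutates and
    returns the report.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable SEs")
    K = report.n_expansions
    if K < 10:
        raise ValueError("too few expansion points to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, K, size=(n_boot, K))
    dt_b = report.delta_true[idx]
    df_b = report.delta_full[idx]
    r2f = _boot_r2(dt_b, df_b)
    ok = r2f > 1e-12

    def metric_se(contrib: np.ndarray) -> np.ndarray:
        se = np.zeros(contrib.shape[0])
        for i in range(contrib.shape[0]):
            r2r = _boot_r2(dt_b, df_b - contrib[i][idx])
            variates = np.zeros(n_boot)
            variates[ok] = 1.0 - r2r[ok] / r2f[ok]
            se[i] = variates.std()
        return se

    report.se_pred = metric_se(report.contrib_pred)
    report.se_inter = metric_se(report.contrib_inter)
    z = _stats.norm.ppf(1.0 - alpha / max(n_comparisons, 1))
    report.sig_pred = (report.t_pred - z * report.se_pred) > threshold
    report.sig_inter = (report.t_inter - z * report.se_inter) > threshold
    if not report.usable:
        report.sig_pred[:] = False
        report.sig_inter[:] = False
    return report


# --------------------------------------------------------- auxiliary metrics
def curvature_metric(model, windows: WindowTensor | np.ndarray, stride: int = 5) -> float:
    """Mean magnitude of the Hessian's action on unit steps through the data.

    For consecutive sampled windows ``x -> x'``, averages ``||H(x) u||`` with
    ``u`` the unit-normalized step — a proxy for the influence of the
    second-order term (zero for a linear model).
    """
    X = windows.flat if isinstance(windows, WindowTensor) else np.atleast_2d(windows)
    samples = X[::stride]
    total, count = 0.0, 0
    for x, x_next in zip(samples[:-1], samples[1:]):
        step = x_next - x
        nrm = np.linalg.norm(step)
        if nrm == 0:
            continue
        H = derivatives_at(model, x).H
        total += float(np.linalg.norm(H @ (step / nrm)))
        count += 1
    if count == 0:
        raise ValueError("no usable consecutive pairs")
    return total / count


def nlc(model, windows: WindowTensor | np.ndarray, stride: int = 5) -> float:
    """Nonlinearity coefficient: linearized output variance over true variance.

    ``E_x[J(x)^T Cov(X) J(x)] / Var(f)`` — approximately 1 for a linear model
    on its data distribution, inflating as the local gradient varies.
    """
    X = windows.flat if isinstance(windows, WindowTensor) else np.atleast_2d(windows)
    samples = X[::stride]
    f = np.asarray(model.predict(samples), float).ravel()
    var_f = f.var()
    if var_f < 1e-12:
        raise UndefinedScoreError("output variance vanishes; NLC undefined")
    cov = np.cov(samples, rowvar=False)
    J = _batch_gradient(model, samples)
    quad = np.einsum("ij,jk,ik->i", J, cov, J)
    return float(quad.mean() / var_f)
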