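"""The per-neuron convolutional encoder network.

Architecture: 80 linear temporal filters spanning the full input window
(so convolution + flatten collapses to a single dense ``D x 80`` projection of
the flattened window, where ``D = history_n * P``), followed by two 64-unit
dense layers with swish activation, feeding a scalar linear output.  Dropout
(rate 0.5) after each dense layer and an L1 penalty on all weights regularize
training; both are inactive at inference, so the forward pass is deterministic
and twice continuously differentiable — the property the Taylor analysis
relies on.

Training minimizes mean squared error plus the L1 penalty with Adam on the
temporally first ``train_fraction`` of the windows; the remainder is the test
partition.  All randomness (init, shuffling, dropout) flows from a single
seed, so two builds/runs with the same seed are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import WindowTensor
from .errors import TrainingError

__all__ = ["EncoderModel", "FitResult", "train_encoder", "build_encoder", "pearson_r"]

N_CONV = 80
N_DENSE = 64


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def swish(z: np.ndarray) -> np.ndarray:
    """Swish activation with beta = 1: ``z * sigmoid(z)``."""
    return z * _sigmoid(z)


def swish_d1(z: np.ndarray) -> np.ndarray:
    """First derivative of swish: ``sig(z) * (1 + z * (1 - sig(z)))``."""
    s = _sigmoid(z)
    return s * (1.0 + z * (1.0 - s))


def swish_d2(z: np.ndarray) -> np.ndarray:
    """Second derivative of swish: ``sig'(z) * (2 + z * (1 - 2 sig(z)))``."""
    s = _sigmoid(z)
    return s * (1.0 - s) * (2.0 + z * (1.0 - 2.0 * s))


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0.0 when either argument is constant."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


@dataclass
class FitResult:
    """Train/test goodness of fit for one trained encoder."""

    train_corr: float
    test_corr: float
    corr_cut: float = 0.5

    @property
    def fit_flag(self) -> bool:
        """Whether the neuron counts as successfully identified."""
        return self.test_corr >= self.corr_cut


class EncoderModel:
    """Three-layer network mapping a flattened causal window to activity.

    Parameters
    ----------
    n_predictors, history_n:
        Define the input dimensionality ``D = history_n * n_predictors``.
    l1_weight:
        Coefficient of the L1 penalty on all weight matrices (not biases).
    dropout_rate:
        Dropout probability after each dense layer during training.
    conv_bias:
        Whether the 80 temporal filters carry bias terms.
    seed:
        Seeds the Glorot-uniform initialization.
    """

    def __init__(
        self,
        n_predictors: int,
        history_n: int,
        l1_weight: float = 1e-3,
        dropout_rate: float = 0.5,
        conv_bias: bool = True,
        seed: int = 0,
    ) -> None:
        if n_predictors < 1:
            raise ValueError("need at least one predictor")
        self.n_predictors = int(n_predictors)
        self.history_n = int(history_n)
        self.l1_weight = float(l1_weight)
        self.dropout_rate = float(dropout_rate)
        self.conv_bias = bool(conv_bias)
        self.seed = int(seed)
        D = self.input_dim
        rng = np.random.default_rng(seed)

        def glorot(n_in: int, n_out: int) -> np.ndarray:
            limit = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-limit, limit, size=(n_in, n_out))

        self.W0 = glorot(D, N_CONV)
        self.b0 = np.zeros(N_CONV)
        self.W1 = glorot(N_CONV, N_DENSE)
        self.b1 = np.zeros(N_DENSE)
        self.W2 = glorot(N_DENSE, N_DENSE)
        self.b2 = np.zeros(N_DENSE)
        self.w3 = glorot(N_DENSE, 1)[:, 0]
        self.b3 = 0.0

    # ------------------------------------------------------------------ basic
    @property
    def input_dim(self) -> int:
        return self.history_n * self.n_predictors

    @property
    def n_params(self) -> int:
        """Trainable parameter count, matching direct enumeration."""
        n = self.W0.size + self.W1.size + self.b1.size
        n += self.W2.size + self.b2.size + self.w3.size + 1
        if self.conv_bias:
            n += self.b0.size
        return n

    def weights(self) -> dict[str, np.ndarray]:
        return {
            "W0": self.W0, "b0": self.b0, "W1": self.W1, "b1": self.b1,
            "W2": self.W2, "b2": self.b2, "w3": self.w3,
            "b3": np.asarray(self.b3),
        }

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.W0 = np.asarray(weights["W0"], float)
        self.b0 = np.asarray(weights["b0"], float)
        self.W1 = np.asarray(weights["W1"], float)
        self.b1 = np.asarray(weights["b1"], float)
        self.W2 = np.asarray(weights["W2"], float)
        self.b2 = np.asarray(weights["b2"], float)
        self.w3 = np.asarray(weights["w3"], float)
        self.b3 = float(np.asarray(weights["b3"]))

    # -------------------------------------------------------------- inference
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout off) on ``(n, D)`` inputs."""
        X = np.atleast_2d(np.asarray(X, float))
        U = X @ self.W0 + self.b0
        A1 = swish(U @ self.W1 + self.b1)
        A2 = swish(A1 @ self.W2 + self.b2)
        return A2 @ self.w3 + self.b3

    def predict_windows(self, windows: WindowTensor) -> np.ndarray:
        return self.predict(windows.flat)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.predict(X)

    # ---------------------------------------------------- input-space autodiff
    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """Gradient of the scalar output w.r.t. each input row; ``(n, D)``."""
        X = np.atleast_2d(np.asarray(X, float))
        U = X @ self.W0 + self.b0
        Z1 = U @ self.W1 + self.b1
        Z2 = swish(Z1) @ self.W2 + self.b2
        G2 = swish_d1(Z2) * self.w3                    # (n, 64)
        G1 = (G2 @ self.W2.T) * swish_d1(Z1)           # (n, 64)
        GU = G1 @ self.W1.T                            # (n, 80)
        return GU @ self.W0.T                          # (n, D)

    def input_hessian(self, x: np.ndarray) -> np.ndarray:
        """Exact Hessian of the output w.r.t. a single input window.

        Because the first layer is linear, ``H = W0 G W0^T`` where ``G`` is the
        Hessian of the dense head with respect to the 80 filter outputs;
        ``G`` follows from closed-form first/second swish derivatives.
        """
        x = np.asarray(x, float).ravel()
        u = x @ self.W0 + self.b0
        z1 = u @ self.W1 + self.b1
        a1 = swish(z1)
        z2 = a1 @ self.W2 + self.b2
        # q_j = df/da1_j ; c_j = d2 contribution through swish curvature of z1
        g2 = swish_d1(z2) * self.w3                    # (64,)
        q = self.W2 @ g2                               # (64,)
        c = swish_d2(z1) * q                           # (64,)
        m = self.w3 * swish_d2(z2)                     # (64,)
        # M = W2 diag(m) W2^T ; P1 = W1 * s'(z1)
        M = (self.W2 * m) @ self.W2.T                  # (64, 64)
        P1 = self.W1 * swish_d1(z1)                    # (80, 64)
        G = (self.W1 * c) @ self.W1.T + P1 @ M @ P1.T  # (80, 80)
        H = self.W0 @ G @ self.W0.T                    # (D, D)
        return 0.5 * (H + H.T)

    def taylor_state(self, x: np.ndarray):
        """Value, gradient and Hessian at one input window (f, J, H)."""
        x = np.asarray(x, float).ravel()
        f = float(self.predict(x[None, :])[0])
        J = self.input_gradient(x[None, :])[0]
        H = self.input_hessian(x)
        return f, J, H

    # ---------------------------------------------------------------- training
    def _loss_and_grads(self, X, y, rng):
        n = X.shape[0]
        keep = 1.0 - self.dropout_rate
        U = X @ self.W0 + self.b0
        Z1 = U @ self.W1 + self.b1
        A1 = swish(Z1)
        if self.dropout_rate > 0:
            m1 = rng.random(A1.shape) < keep
            A1d = A1 * m1 / keep
        else:
            A1d = A1
        Z2 = A1d @ self.W2 + self.b2
        A2 = swish(Z2)
        if self.dropout_rate > 0:
            m2 = rng.random(A2.shape) < keep
            A2d = A2 * m2 / keep
        else:
            A2d = A2
        yhat = A2d @ self.w3 + self.b3
        resid = yhat - y
        mse = float((resid ** 2).mean())

        d_yhat = 2.0 * resid / n
        g_w3 = A2d.T @ d_yhat
        g_b3 = float(d_yhat.sum())
        dA2 = np.outer(d_yhat, self.w3)
        if self.dropout_rate > 0:
            dA2 = dA2 * m2 / keep
        dZ2 = dA2 * swish_d1(Z2)
        g_W2 = A1d.T @ dZ2
        g_b2 = dZ2.sum(axis=0)
        dA1 = dZ2 @ self.W2.T
        if self.dropout_rate > 0:
            dA1 = dA1 * m1 / keep
        dZ1 = dA1 * swish_d1(Z1)
        g_W1 = U.T @ dZ1
        g_b1 = dZ1.sum(axis=0)
        dU = dZ1 @ self.W1.T
        g_W0 = X.T @ dU
        g_b0 = dU.sum(axis=0)

        if self.l1_weight > 0:
            l1 = self.l1_weight
            g_W0 = g_W0 + l1 * np.sign(self.W0)
            g_W1 = g_W1 + l1 * np.sign(self.W1)
            g_W2 = g_W2 + l1 * np.sign(self.W2)
            g_w3 = g_w3 + l1 * np.sign(self.w3)
        grads = {"W0": g_W0, "b0": g_b0, "W1": g_W1, "b1": g_b1,
                 "W2": g_W2, "b2": g_b2, "w3": g_w3, "b3": g_b3}
        if not self.conv_bias:
            grads["b0"] = np.zeros_like(self.b0)
        return mse, grads

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        n_epochs: int = 100,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        seed: int | None = None,
    ) -> None:
        """Adam optimization of MSE + L1 over the given (training) samples."""
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        params = ["W0", "b0", "W1", "b1", "W2", "b2", "w3", "b3"]
        m = {p: np.zeros_like(np.asarray(getattr(self, p), float)) for p in params}
        v = {p: np.zeros_like(np.asarray(getattr(self, p), float)) for p in params}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = X.shape[0]
        for _ in range(n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                mse, grads = self._loss_and_grads(X[idx], y[idx], rng)
                if not np.isfinite(mse):
                    raise TrainingError(
                        f"non-finite loss at step {step} (lr={learning_rate}); "
                        "check input scaling"
                    )
                step += 1
                corr1 = 1.0 - beta1 ** step
                corr2 = 1.0 - beta2 ** step
                for p in params:
                    g = grads[p]
                    m[p] = beta1 * m[p] + (1 - beta1) * g
                    v[p] = beta2 * v[p] + (1 - beta2) * np.square(g)
                    update = learning_rate * (m[p] / corr1) / (np.sqrt(v[p] / corr2) + eps)
                    if p == "b3":
                        self.b3 = float(self.b3 - update)
                    else:
                        setattr(self, p, getattr(self, p) - update)


def build_encoder(
    n_predictors: int,
    history_n: int = 50,
    l1_weight: float = 1e-3,
    seed: int = 0,
    conv_bias: bool = True,
    dropout_rate: float = 0.5,
) -> EncoderModel:
    """Construct an initialized (untrained) encoder network."""
    return EncoderModel(
        n_predictors,
        history_n,
        l1_weight=l1_weight,
        dropout_rate=dropout_rate,
        conv_bias=conv_bias,
        seed=seed,
    )


def train_encoder(
    model: EncoderModel,
    windows: WindowTensor | np.ndarray,
    response: np.ndarray,
    n_epochs: int = 100,
    train_fraction: float = 2.0 / 3.0,
    batch_size: int = 256,
    learning_rate: float = 1e-3,
    corr_cut: float = 0.5,
    seed: int | None = None,
) -> FitResult:
    """Train on the temporally first fraction of windows, test on the rest.

    ``response`` must be aligned with the window rows (one target per window,
    i.e. the activity at each window's final sample).  The split is strictly
    temporal — no shuffling across the train/test boundary — so test
    correlations measure generalization to unseen experimental time.
    """
    X = windows.flat if isinstance(windows, WindowTensor) else np.asarray(windows, float)
    y = np.asarray(response, float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} windows but {y.shape[0]} response samples")
    n_train = int(round(X.shape[0] * train_fraction))
    n_train = min(max(n_train, 1), X.shape[0] - 1)
    model.fit(X[:n_train], y[:n_train], n_epochs=n_epochs, batch_size=batch_size,
              learning_rate=learning_rate, seed=seed)
    yhat = model.predict(X)
    return FitResult(
        train_corr=pearson_r(yhat[:n_train], y[:n_train]),
        test_corr=pearson_r(yhat[n_train:], y[n_train:]),
        corr_cut=corr_cut,
    )
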