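"""Shared fixtures: hand-differentiable oracle models and trained encoders.

The polynomial models implement the same differentiable-model protocol as the
encoder (``predict`` / ``taylor_state`` / ``input_gradient``) with derivatives
written down by hand, so Taylor-analysis code paths can be validated against
closed forms independently of network training.
"""

from __future__ import annotations

import numpy as np
import pytest

from mine.data import make_windows, standardize
from mine.encoder import EncoderModel, train_encoder
from mine.synthetic import calcium_kernel, gen_smooth_predictor


class LinearModel:
    """f(x) = w.x + b with exact derivatives."""

    def __init__(self, w: np.ndarray, b: float = 0.0):
        self.w = np.asarray(w, float)
        self.b = float(b)

    def predict(self, X):
        return np.atleast_2d(X) @ self.w + self.b

    def input_gradient(self, X):
        return np.tile(self.w, (np.atleast_2d(X).shape[0], 1))

    def taylor_state(self, x):
        D = self.w.shape[0]
        return float(x @ self.w + self.b), self.w.copy(), np.zeros((D, D))


class QuadraticModel:
    """f(x) = (w.x)^2: J = 2 (w.x) w, H = 2 w w^T."""

    def __init__(self, w: np.ndarray):
        self.w = np.asarray(w, float)

    def predict(self, X):
        return (np.atleast_2d(X) @ self.w) ** 2

    def input_gradient(self, X):
        u = np.atleast_2d(X) @ self.w
        return 2.0 * u[:, None] * self.w

    def taylor_state(self, x):
        u = float(x @ self.w)
        return u * u, 2.0 * u * self.w, 2.0 * np.outer(self.w, self.w)


class ProductModel:
    """f(x) = (a.x)(b.x): a gated/multiplicative unit with exact derivatives."""

    def __init__(self, a: np.ndarray, b: np.ndarray):
        self.a = np.asarray(a, float)
        self.b = np.asarray(b, float)

    def predict(self, X):
        X = np.atleast_2d(X)
        return (X @ self.a) * (X @ self.b)

    def input_gradient(self, X):
        X = np.atleast_2d(X)
        return np.outer(X @ self.b, self.a) + np.outer(X @ self.a, self.b)

    def taylor_state(self, x):
        ua, ub = float(x @ self.a), float(x @ self.b)
        H = np.outer(self.a, self.b) + np.outer(self.b, self.a)
        return ua * ub, ub * self.a + ua * self.b, H


class AdditiveSaturatingModel:
    """f(x) = tanh(a.x) + tanh(b.x): nonlinear but with no a-b interaction."""

    def __init__(self, a: np.ndarray, b: np.ndarray):
        self.a = np.asarray(a, float)
        self.b = np.asarray(b, float)

    def predict(self, X):
        X = np.atleast_2d(X)
        return np.tanh(X @ self.a) + np.tanh(X @ self.b)

    def taylor_state(self, x):
        ua, ub = float(x @ self.a), float(x @ self.b)
        J = (1 - np.tanh(ua) ** 2) * self.a + (1 - np.tanh(ub) ** 2) * self.b
        H = -2 * np.tanh(ua) * (1 - np.tanh(ua) ** 2) * np.outer(self.a, self.a)
        H += -2 * np.tanh(ub) * (1 - np.tanh(ub) ** 2) * np.outer(self.b, self.b)
        f = np.tanh(ua) + np.tanh(ub)
        return f, J, H


@pytest.fixture(scope="session")
def oracle_rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def linear_task():
    """Noiseless linear-convolution task plus the encoder trained on it.

    The response is the stimulus convolved with a known calcium kernel, so
    the composed stimulus->response filter is known exactly and the trained
    network should be essentially linear.
    """
    T = 2000
    stim = gen_smooth_predictor(T, seed=11)
    kernel = calcium_kernel(2.5, 0.2)
    resp = standardize(np.convolve(stim, kernel, mode="full")[:T])
    windows = make_windows(stim[None, :], 50)
    y = resp[windows.t_index]
    model = EncoderModel(1, 50, seed=21)
    fit = train_encoder(model, windows, y, n_epochs=60, seed=22)
    return {
        "stimulus": stim,
        "response": resp,
        "kernel": kernel,
        "windows": windows,
        "y": y,
        "model": model,
        "fit": fit,
    }
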