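"""Time-base bookkeeping, trace standardization and causal input windows.

The encoder predicts activity at time ``t`` from predictor values over
``[t - history_n + 1, t]`` — a strictly causal window whose last lag is the
predicted sample itself.  Everything downstream (Taylor expansion, receptive
fields, Volterra kernels) indexes into these flattened windows, so the layout
is fixed here once: a window is an ``(history_n, P)`` array, flattened C-order,
i.e. element ``l * P + p`` is predictor ``p`` at lag position ``l`` (``l = 0``
oldest, ``l = history_n - 1`` the present sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "TimeBase",
    "PredictorSet",
    "WindowTensor",
    "standardize",
    "is_standardized",
    "cyclic_permute_control",
]


@dataclass(frozen=True)
class TimeBase:
    """Sampling parameters of the common time base.

    Parameters
    ----------
    dt:
        Seconds per sample (default 0.2, i.e. 5 Hz acquisition).
    history_s:
        Length of the receptive window in seconds (default 10 s).
    """

    dt: float = 0.2
    history_s: float = 10.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.history_n < 2:
            raise ValueError("history window must span at least 2 samples")

    @property
    def history_n(self) -> int:
        """Window length in samples."""
        return int(round(self.history_s / self.dt))


def standardize(trace: np.ndarray) -> np.ndarray:
    """Z-score a trace to zero mean and unit (population) standard deviation.

    Raises
    ------
    DegenerateInputError
        If the trace has fewer than 2 samples or zero variance.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise DegenerateInputError("need at least 2 samples to standardize")
    sd = trace.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot standardize a zero-variance trace")
    return (trace - trace.mean()) / sd


def is_standardized(trace: np.ndarray, mean_tol: float = 1e-2, sd_tol: float = 1e-2) -> bool:
    """Check whether a trace is (approximately) z-scored."""
    trace = np.asarray(trace, dtype=float)
    return bool(abs(trace.mean()) < mean_tol and abs(trace.std() - 1.0) < sd_tol)


def _warn_if_raw(trace: np.ndarray, what: str) -> None:
    if not is_standardized(trace):
        warnings.warn(
            f"{what} does not appear to be z-scored (mean 0, SD 1); "
            "results assume standardized inputs",
            UserWarning,
            stacklevel=3,
        )


@dataclass
class PredictorSet:
    """A named bundle of predictor traces on a common time base.

    ``values`` is a ``(P, T)`` array; each row is one predictor.
    """

    names: list[str]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.names) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.names)} names for {self.values.shape[0]} traces"
            )
        if self.standardized:
            means = self.values.mean(axis=1)
            sds = self.values.std(axis=1)
            if np.abs(means).max() >= 1e-6 or np.abs(sds - 1).max() >= 1e-3:
                raise ValueError("traces marked standardized are not z-scored")

    @classmethod
    def from_traces(cls, names, traces, standardize_traces: bool = True) -> "PredictorSet":
        values = np.vstack([np.asarray(t, dtype=float) for t in traces])
        if standardize_traces:
            values = np.vstack([standardize(v) for v in values])
        return cls(list(names), values, standardized=standardize_traces)

    @property
    def n_predictors(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class WindowTensor:
    """Causal input windows: ``windows[k, l, p]`` = predictor ``p`` at lag ``l``.

    Row ``k`` is the input used to predict activity at time ``t_index[k]``;
    its last lag position holds the sample at that same time.
    """

    windows: np.ndarray
    t_index: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def history_n(self) -> int:
        return self.windows.shape[1]

    @property
    def n_predictors(self) -> int:
        return self.windows.shape[2]

    @property
    def flat(self) -> np.ndarray:
        """Windows flattened to ``(n_windows, history_n * P)`` (C-order)."""
        return self.windows.reshape(self.n_windows, -1)


def make_windows(predictors: PredictorSet | np.ndarray, history_n: int) -> WindowTensor:
    """Slice predictor traces into causal, fully overlapping input windows.

    Produces ``T - history_n + 1`` windows; window ``k`` covers samples
    ``k .. k + history_n - 1`` and is aligned to predict the response at the
    window's final sample.  No future samples ever enter a window.
    """
    values = predictors.values if isinstance(predictors, PredictorSet) else np.atleast_2d(predictors)
    P, T = values.shape
    if history_n < 2:
        raise ValueError("history_n must be >= 2")
    if T < history_n:
        raise InsufficientDataError(
            f"need at least history_n={history_n} samples, got {T}"
        )
    n_win = T - history_n + 1
    vt = np.ascontiguousarray(values.T)  # (T, P)
    windows = np.lib.stride_tricks.sliding_window_view(vt, history_n, axis=0)
    # sliding_window_view gives (n_win, P, history_n); reorder to (n_win, history_n, P)
    windows = np.ascontiguousarray(np.swapaxes(windows, 1, 2))
    return WindowTensor(windows, np.arange(history_n - 1, T))


def predictor_index_blocks(history_n: int, n_predictors: int) -> list[np.ndarray]:
    """Flat-window index arrays belonging to each predictor.

    With C-order flattening of ``(history_n, P)`` windows, predictor ``p``
    occupies indices ``p, p + P, p + 2P, ...``.
    """
    return [np.arange(history_n) * n_predictors + p for p in range(n_predictors)]


def cyclic_permute_control(response: np.ndarray, shift: int | None = None) -> np.ndarray:
    """Rotate an activity trace forward in time with wrap-around.

    The rotation (default: one third of the trace length) preserves the
    marginal distribution of the trace but destroys its temporal relation to
    the predictors, yielding a negative-control response.
    """
    response = np.asarray(response, dtype=float)
    T = response.shape[-1]
    if T < 3:
        raise InsufficientDataError("need at least 3 samples for a control rotation")
    if shift is None:
        shift = T // 3
    return np.roll(response, shift, axis=-1)
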