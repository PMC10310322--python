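"""Synthetic ground-truth data: predictors, responses, mixtures, LN-LN systems.

Three families of simulations, mirroring the benchmarks the method was
validated on:

* A ground-truth catalogue: smooth "sensory" predictors built from mixed
  sine/square/triangle waves, Poisson "motor" event predictors, and responses
  formed by linear or nonlinear transforms (and products) of the predictors,
  convolved with a calcium kernel and corrupted with i.i.d. Gaussian noise.
* Linear/nonlinear mixing and randomized labelled transform cases used to
  calibrate the linearity classifier (ROC analysis).
* A two-pathway LN-LN system: one stimulus filtered by two orthogonal 50-tap
  kernels whose outputs pass through an asymmetric ("linear") and a symmetric
  ("nonlinear") static nonlinearity before summation — the benchmark for
  receptive-field recovery.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .data import PredictorSet, standardize
from .errors import ConfigError

__all__ = [
    "gen_smooth_predictor",
    "gen_event_predictor",
    "calcium_kernel",
    "ResponseModel",
    "GroundTruthSpec",
    "generate_ground_truth",
    "make_response",
    "gen_mixture",
    "MIXTURE_TRANSFORMS",
    "RocCase",
    "gen_roc_cases",
    "LNLNSystem",
    "simulate_lnln",
    "filter_to_window_layout",
]

ZEBRAFISH_BAND_S = (13.0, 200.0)  # component periods used for the in-vivo stimuli


# --------------------------------------------------------------------- predictors
def gen_smooth_predictor(
    T: int,
    dt: float = 0.2,
    period_range_s: tuple[float, float] = ZEBRAFISH_BAND_S,
    n_components: int = 5,
    kinds: tuple[str, ...] = ("sine", "square", "triangle"),
    seed: int | np.random.Generator = 0,
    standardize_trace: bool = True,
    amp_range: tuple[float, float] = (0.5, 1.5),
) -> np.ndarray:
    """Band-limited smooth trace from random sine/square/triangle components.

    Component periods are drawn log-uniformly from ``period_range_s``;
    amplitudes and phases are random.  Restrict ``kinds`` to ``("sine",)`` for
    the purely sinusoidal stimulus variant (all spectral power then falls
    inside the configured band; square/triangle waves add harmonics).
    By default the trace is standardized; ``standardize_trace=False`` returns
    the raw wave mixture (SD grows with the number of components), which is
    what response-generating nonlinearities are applied to.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(T) * dt
    lo, hi = period_range_s
    trace = np.zeros(T)
    for _ in range(n_components):
        period = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        amp = rng.uniform(*amp_range)
        phase = rng.uniform(0, 2 * np.pi)
        arg = 2 * np.pi * t / period + phase
        kind = kinds[rng.integers(len(kinds))]
        if kind == "sine":
            comp = np.sin(arg)
        elif kind == "square":
            comp = _signal.square(arg)
        elif kind == "triangle":
            comp = _signal.sawtooth(arg, width=0.5)
        else:
            raise ConfigError(f"unknown waveform kind {kind!r}")
        trace += amp * comp
    return standardize(trace) if standardize_trace else trace


def gen_event_predictor(
    T: int,
    rate_hz: float = 0.1,
    dt: float = 0.2,
    scaled: bool = False,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sparse Poisson event train; optionally with N(0, 1)-scaled amplitudes.

    Events occur independently per sample with probability ``rate_hz * dt``.
    Unscaled traces are in {0, 1}; scaled traces multiply each event with a
    standard-normal draw (modeling directed, stochastic movements).
    Returned raw (not standardized) so event sparsity is preserved.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    events = (rng.random(T) < rate_hz * dt).astype(float)
    if scaled:
        events = events * rng.standard_normal(T)
    return events


def calcium_kernel(tau_s: float = 2.5, dt: float = 0.2, n_taus: float = 5.0) -> np.ndarray:
    """Single-exponential calcium-indicator impulse response (unit area)."""
    if tau_s <= 0:
        raise ValueError("tau must be positive")
    t = np.arange(0, tau_s * n_taus, dt)
    k = np.exp(-t / tau_s)
    return k / k.sum()


def _causal_convolve(trace: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(trace, kernel, mode="full")[: trace.shape[0]]


# ---------------------------------------------------------------------- responses
@dataclass(frozen=True)
class ResponseModel:
    """Deterministic transform turning predictors into a noiseless response.

    ``kind`` is one of 'linear', 'rect', 'abs', 'deriv', 'tanh_sq_cube',
    'event', 'product'; ``sources`` names the predictor(s) it reads.
    """

    kind: str
    sources: tuple[str, ...]

    def transform(self, predictors: PredictorSet) -> np.ndarray:
        traces = [predictors.values[predictors.names.index(s)] for s in self.sources]
        x = traces[0]
        if self.kind == "linear":
            return x.copy()
        if self.kind == "rect":
            return np.maximum(x, 0.0)
        if self.kind == "abs":
            return np.abs(x)
        if self.kind == "deriv":
            return np.gradient(x)
        if self.kind == "tanh_sq_cube":
            return np.tanh(x ** 3) ** 2
        if self.kind == "event":
            return x.copy()
        if self.kind == "product":
            if len(traces) != 2:
                raise ConfigError("product responses need exactly two sources")
            return np.maximum(traces[0], 0.0) * np.maximum(traces[1], 0.0)
        raise ConfigError(f"unknown response kind {self.kind!r}")

    @property
    def label(self) -> str:
        return f"{self.kind}({','.join(self.sources)})"


def default_catalogue() -> list[ResponseModel]:
    """The ground-truth response types: single-predictor transforms, event
    responses, and a rectified product (coincidence) response."""
    return [
        ResponseModel("linear", ("S1",)),
        ResponseModel("rect", ("S1",)),
        ResponseModel("abs", ("S1",)),
        ResponseModel("deriv", ("S1",)),
        ResponseModel("tanh_sq_cube", ("S1",)),
        ResponseModel("event", ("M1",)),
        ResponseModel("event", ("M2",)),
        ResponseModel("product", ("S1", "S2")),
    ]


def make_response(
    predictors: PredictorSet,
    model: ResponseModel,
    ca_tau_s: float = 2.5,
    noise_sd: float = 0.25,
    dt: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Transform -> calcium-kernel convolution -> additive Gaussian noise.

    The noiseless signal is standardized before noise is added, so
    ``noise_sd`` is expressed as a fraction of the pre-noise response SD.
    The returned trace is standardized again (encoder inputs are z-scored).
    """
    rng = np.random.default_rng(seed)
    sig = model.transform(predictors)
    if ca_tau_s > 0:
        sig = _causal_convolve(sig, calcium_kernel(ca_tau_s, dt))
    if sig.std() > 1e-12:
        sig = standardize(sig)
    else:
        sig = np.zeros_like(sig)
    out = sig + noise_sd * rng.standard_normal(sig.shape[0])
    return standardize(out)


@dataclass
class GroundTruthSpec:
    """Configuration of the full ground-truth dataset."""

    T: int = 3600
    dt: float = 0.2
    n_smooth: int = 2
    n_event: int = 2
    event_rate_hz: float = 0.1
    ca_tau_s: float = 2.5
    noise_sd: float = 0.25
    catalogue: list[ResponseModel] = field(default_factory=default_catalogue)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.ca_tau_s <= 0:
            raise ValueError("noise_sd must be >= 0 and ca_tau_s > 0")


def generate_ground_truth(spec: GroundTruthSpec) -> tuple[PredictorSet, dict[str, np.ndarray]]:
    """Build the predictor set (S1, S2 smooth; M1 Poisson; M2 scaled Poisson)
    and one response per catalogue entry.  Predictors and responses are
    standardized and share the time base."""
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(spec.n_smooth + spec.n_event + len(spec.catalogue))
    names, traces = [], []
    for i in range(spec.n_smooth):
        names.append(f"S{i + 1}")
        traces.append(gen_smooth_predictor(spec.T, spec.dt, seed=np.random.default_rng(child[i])))
    for j in range(spec.n_event):
        names.append(f"M{j + 1}")
        traces.append(
            gen_event_predictor(
                spec.T, spec.event_rate_hz, spec.dt, scaled=(j == 1),
                seed=np.random.default_rng(child[spec.n_smooth + j]),
            )
        )
    predictors = PredictorSet.from_traces(names, traces, standardize_traces=True)
    responses = {}
    for k, model in enumerate(spec.catalogue):
        rng = np.random.default_rng(child[spec.n_smooth + spec.n_event + k])
        responses[model.label] = make_response(
            predictors, model, spec.ca_tau_s, spec.noise_sd, spec.dt, seed=rng
        )
    return predictors, responses


# ----------------------------------------------------------------------- mixtures
MIXTURE_TRANSFORMS = {
    "tanh_sq_cube": lambda x: np.tanh(x ** 3) ** 2,
    "derivative": np.gradient,
    "softplus": lambda x: np.logaddexp(0.0, 2.0 * x),
    "shift": lambda x: np.roll(x, 5),
}


def gen_mixture(predictor: np.ndarray, transform: str, fraction: float) -> np.ndarray:
    """Mix a linear response with a transformed copy of the same predictor.

    ``response = (1 - fraction) * z(x) + fraction * z(g(x))`` with both
    components standardized before mixing.  Nonlinear ``g`` injects a
    controlled amount of nonlinearity; the 'derivative' and 'shift' transforms
    are themselves linear and serve as controls.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if transform not in MIXTURE_TRANSFORMS:
        raise ConfigError(f"unknown mixture transform {transform!r}")
    x = standardize(np.asarray(predictor, float))
    g = standardize(MIXTURE_TRANSFORMS[transform](x))
    return standardize((1.0 - fraction) * x + fraction * g)


# ---------------------------------------------------------------------- ROC cases
@dataclass
class RocCase:
    """One labelled linearity-classification case: 5 stimuli, one response
    driven only by the first stimulus (the rest are distractors)."""

    stimuli: np.ndarray  # (5, T), standardized
    response: np.ndarray  # (T,), standardized
    label: str  # 'linear' | 'nonlinear'
    kind: str  # generating transform


def _double_exponential_filter(rng: np.random.Generator, dt: float) -> np.ndarray:
    """Random causal biphasic kernel: (1 - e^(-t/tau_rise)) * e^(-t/tau_decay)."""
    tau_rise = rng.uniform(0.1, 0.5)
    tau_decay = rng.uniform(0.5, 2.0)
    t = np.arange(0, 5.0 * tau_decay, dt)
    k = (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
    return k / np.abs(k).max()


def gen_roc_cases(
    n_sets: int = 500,
    T: int = 1650,
    dt: float = 0.2,
    n_stimuli: int = 5,
    seed: int = 0,
) -> list[RocCase]:
    """Labelled cases for ROC calibration of the linearity score.

    Per set: ``n_stimuli`` random smooth stimuli and four responses of the
    first stimulus — two linear (differencing; convolution with a random
    double-exponential filter) and two nonlinear (variable-strength softplus
    rectification via shift+scale; tanh raised to a random integer power
    1..5).  Transforms are applied to the *raw* wave mixture, with component
    amplitudes drawn U(1, 3) (trace SD ~ 3) so that the saturating and
    rectifying transforms operate deep in their nonlinear range — the premise
    of the labels is that nonlinear-tagged transforms are decisively
    nonlinear.  Stimuli and responses are standardized afterwards.  Labels
    follow construction: 2 linear + 2 nonlinear per set.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    ss = np.random.SeedSequence(seed)
    cases: list[RocCase] = []
    for child in ss.spawn(n_sets):
        rng = np.random.default_rng(child)
        raw = [
            gen_smooth_predictor(
                T, dt, seed=rng, standardize_trace=False, amp_range=(1.0, 3.0)
            )
            for _ in range(n_stimuli)
        ]
        stimuli = np.vstack([standardize(r) for r in raw])
        s = raw[0]
        variants = [
            ("linear", "diff", np.gradient(s)),
            ("linear", "double_exp", _causal_convolve(s, _double_exponential_filter(rng, dt))),
        ]
        scale = rng.uniform(0.5, 4.0)
        shift = rng.uniform(-1.0, 1.0)
        variants.append(("nonlinear", "softplus", np.logaddexp(0.0, scale * (s - shift))))
        power = int(rng.integers(1, 6))
        variants.append(("nonlinear", f"tanh_pow{power}", np.tanh(s) ** power))
        for label, kind, resp in variants:
            cases.append(RocCase(stimuli, standardize(resp), label, kind))
    return cases


# ------------------------------------------------------------------ LN-LN system
def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass
class LNLNSystem:
    """Two-pathway LN-LN simulator with orthogonal 50-tap filters.

    The "linear" pathway applies ``g_linear(x) = x / (1 + exp(-5x))`` — an
    asymmetric, near-identity-for-large-x nonlinearity whose filter is
    expected to surface in the first-order kernel.  The "nonlinear" pathway
    applies the even function ``g_nonlinear(x) = (0.25 - e^x/(1+e^x)^2) * 15``,
    whose filter can only appear in the second-order kernel.  Filter indices
    are lags: ``f[0]`` weights the current sample.
    """

    f_linear: np.ndarray
    f_nonlinear: np.ndarray

    def __post_init__(self) -> None:
        self.f_linear = np.asarray(self.f_linear, float)
        self.f_nonlinear = np.asarray(self.f_nonlinear, float)
        if self.f_linear.shape != self.f_nonlinear.shape:
            raise ValueError("filters must share a length")

    @staticmethod
    def g_linear(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return x / (1.0 + np.exp(-5.0 * np.clip(x, -100, 100)))

    @staticmethod
    def g_nonlinear(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -100, 100)))
        return (0.25 - sig * (1.0 - sig)) * 15.0

    @classmethod
    def preset(cls, name: str = "a", n_taps: int = 50, match_variance: bool = True) -> "LNLNSystem":
        """Construct an orthogonal filter pair.

        Preset 'a': biphasic linear filter, unimodal nonlinear filter.
        Preset 'b': slow unimodal linear filter, damped-oscillation nonlinear
        filter.  The linear filter is Gram-Schmidt-projected against the
        nonlinear one, then (optionally) rescaled so both pathway responses
        have matched variance under a white-noise stimulus — the stated
        design goal of the constant in ``g_nonlinear``.
        """
        t = np.arange(n_taps)
        if name == "a":
            f_non = np.exp(-((t - 22.0) ** 2) / (2 * 6.0 ** 2))
            f_lin = np.exp(-((t - 12.0) ** 2) / (2 * 4.0 ** 2)) - np.exp(
                -((t - 28.0) ** 2) / (2 * 6.0 ** 2)
            )
        elif name == "b":
            f_non = np.exp(-t / 12.0) * np.sin(2 * np.pi * t / 20.0)
            f_lin = np.sin(np.pi * t / (n_taps - 1)) ** 2
        else:
            raise ConfigError(f"unknown LN-LN preset {name!r}")
        f_non = _unit(f_non)
        f_lin = f_lin - (f_lin @ f_non) * f_non
        f_lin = _unit(f_lin)
        if match_variance:
            f_lin = f_lin * cls._variance_matching_scale()
        return cls(f_lin, f_non)

    @classmethod
    def _variance_matching_scale(cls) -> float:
        """Scale ``c`` for the (unit-norm) linear filter such that
        Var[g_linear(c u)] = Var[g_nonlinear(u)] for u ~ N(0, 1), computed by
        Gauss-Hermite quadrature."""
        nodes, weights = np.polynomial.hermite_e.hermegauss(101)
        w = weights / weights.sum()

        def var_of(fun, scale=1.0):
            vals = fun(scale * nodes)
            mean = w @ vals
            return w @ (vals - mean) ** 2

        target = var_of(cls.g_nonlinear)
        lo, hi = 0.1, 20.0
        for _ in range(80):  # bisection; var_lin is increasing in the scale
            mid = 0.5 * (lo + hi)
            if var_of(cls.g_linear, mid) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def respond(self, stimulus: np.ndarray) -> np.ndarray:
        """Noiseless response: sum of the two filtered-then-transformed paths."""
        u_lin = _causal_convolve(stimulus, self.f_linear)
        u_non = _causal_convolve(stimulus, self.f_nonlinear)
        return self.g_linear(u_lin) + self.g_nonlinear(u_non)

    def pathway_responses(self, stimulus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u_lin = _causal_convolve(stimulus, self.f_linear)
        u_non = _causal_convolve(stimulus, self.f_nonlinear)
        return self.g_linear(u_lin), self.g_nonlinear(u_non)


def simulate_lnln(
    system: LNLNSystem,
    stimulus_kind: str = "smooth",
    T: int = 3600,
    dt: float = 0.2,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the LN-LN system; returns (stimulus, response).

    ``stimulus_kind`` is 'white' (S_t ~ N(0,1)) or 'smooth' (the standardized
    mixed sine/square/triangle wave generator — its occasional edges carry
    the broadband content that keeps 50-tap filters identifiable).
    ``noise_sd`` adds i.i.d. Gaussian output noise in units of the noiseless
    response SD.
    """
    rng = np.random.default_rng(seed)
    if stimulus_kind == "white":
        stimulus = rng.standard_normal(T)
    elif stimulus_kind == "smooth":
        stimulus = gen_smooth_predictor(T, dt, seed=rng)
    else:
        raise ConfigError(f"unknown stimulus kind {stimulus_kind!r}")
    response = system.respond(stimulus)
    if noise_sd > 0:
        response = response + noise_sd * response.std() * rng.standard_normal(T)
    return stimulus, response


def filter_to_window_layout(f: np.ndarray, history_n: int | None = None) -> np.ndarray:
    """Convert a lag-indexed filter (index 0 = current sample) to the window
    layout used by the encoder (last position = current sample)."""
    f = np.asarray(f, float)
    if history_n is not None and f.shape[0] != history_n:
        out = np.zeros(history_n)
        out[: min(history_n, f.shape[0])] = f[: min(history_n, f.shape[0])]
        f = out
    return f[::-1]
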