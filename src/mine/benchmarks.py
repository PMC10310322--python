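"""End-to-end benchmark computations on synthetic data.

These routines recompute the framework's headline simulation results from
scratch: the ROC calibration of the linearity score, the error rates of the
0.8-threshold classifier, effective degrees of freedom of the encoder on the
LN-LN task, and the receptive-field recovery comparison against direct
Volterra fits.  They are used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import make_windows, standardize
from .encoder import EncoderModel, pearson_r, train_encoder
from .receptive_fields import build_q_matrix, match_pdms
from .synthetic import (
    LNLNSystem,
    RocCase,
    filter_to_window_layout,
    gen_roc_cases,
    simulate_lnln,
)
from .taylor import approximation_scores, derivatives_at
from .volterra import build_design, fit_volterra, simulation_edf

__all__ = [
    "linearity_scores",
    "roc_auc",
    "error_rates",
    "LinearityBenchmark",
    "run_linearity_benchmark",
    "lnln_edf",
    "benchmark_recovery",
]

# The benchmarks use the default simulation length (3600 samples = 12 min at
# 5 Hz) and the full 100-epoch training budget; desk scaling is purely in the
# number of cases/replicates.
ROC_T = 3600
ROC_EPOCHS = 100


def linearity_scores(
    cases: list[RocCase],
    history_n: int = 50,
    n_epochs: int = ROC_EPOCHS,
    seed: int = 0,
) -> pd.DataFrame:
    """Train one encoder per labelled case and score its linearity.

    Returns a frame with the generating transform, the true label and the
    linear-approximation score (LAS) of each fitted model.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for case, child in zip(cases, ss.spawn(len(cases))):
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        windows = make_windows(case.stimuli, history_n)
        y = case.response[windows.t_index]
        model = EncoderModel(case.stimuli.shape[0], history_n, seed=child_seed)
        fit = train_encoder(model, windows, y, n_epochs=n_epochs, seed=child_seed + 1)
        scores = approximation_scores(model, windows)
        rows.append(
            {
                "kind": case.kind,
                "label": case.label,
                "las": scores.las,
                "sos": scores.sos,
                "test_corr": fit.test_corr,
            }
        )
    return pd.DataFrame(rows)


def roc_auc(scores: pd.DataFrame) -> float:
    """Probability that a nonlinear case's LAS ranks below a linear case's.

    This is the area under the ROC curve of the "nonlinear" classifier that
    thresholds the linear-approximation score (ties count half).
    """
    lin = scores.loc[scores["label"] == "linear", "las"].to_numpy()
    non = scores.loc[scores["label"] == "nonlinear", "las"].to_numpy()
    if lin.size == 0 or non.size == 0:
        raise ValueError("need both linear and nonlinear cases")
    diff = lin[:, None] - non[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def error_rates(scores: pd.DataFrame, threshold: float = 0.8) -> tuple[float, float]:
    """(FPR, FNR) of the nonlinearity call ``LAS < threshold``.

    A false positive is a linear case classified nonlinear; a false negative
    a nonlinear case classified linear.
    """
    lin = scores.loc[scores["label"] == "linear", "las"].to_numpy()
    non = scores.loc[scores["label"] == "nonlinear", "las"].to_numpy()
    fpr = float((lin < threshold).mean())
    fnr = float((non >= threshold).mean())
    return fpr, fnr


@dataclass
class LinearityBenchmark:
    """Outcome of the ROC calibration benchmark."""

    scores: pd.DataFrame
    auc: float
    fpr: float
    fnr: float


def run_linearity_benchmark(
    n_sets: int = 25,
    T: int = ROC_T,
    n_epochs: int = ROC_EPOCHS,
    seed: int = 0,
) -> LinearityBenchmark:
    """Generate labelled cases, train encoders, and compute AUC and error rates.

    Each set contributes 2 linear and 2 nonlinear cases, so ``n_sets = 25``
    yields the desk-scale 50 + 50 case design.
    """
    cases = gen_roc_cases(n_sets=n_sets, T=T, seed=seed)
    scores = linearity_scores(cases, n_epochs=n_epochs, seed=seed + 1)
    fpr, fnr = error_rates(scores)
    return LinearityBenchmark(scores=scores, auc=roc_auc(scores), fpr=fpr, fnr=fnr)


def lnln_edf(
    n_reps: int = 20,
    T: int = 3600,
    noise_sd: float = 0.25,
    n_epochs: int = 100,
    preset: str = "a",
    seed: int = 0,
) -> float:
    """Effective degrees of freedom of the encoder on the LN-LN task.

    A fixed smooth stimulus and noiseless LN-LN response define the signal;
    across replicates only the additive output noise is redrawn and the
    encoder retrained with default sparsity/dropout/epoch settings.  The
    covariance formula then yields the df estimate over the training samples.
    """
    system = LNLNSystem.preset(preset)
    stimulus, response = simulate_lnln(system, "smooth", T=T, seed=seed)
    windows = make_windows(standardize(stimulus)[None, :], 50)
    signal = standardize(response)[windows.t_index]
    n_train = int(round(windows.n_windows * 2.0 / 3.0))
    Xtr = windows.flat[:n_train]

    def fit_predict(y: np.ndarray, rep_seed: int) -> np.ndarray:
        model = EncoderModel(1, 50, seed=rep_seed)
        model.fit(Xtr, y, n_epochs=n_epochs, seed=rep_seed + 1)
        return model.predict(Xtr)

    return simulation_edf(
        fit_predict, signal[:n_train], noise_sd=noise_sd, n_reps=n_reps, seed=seed + 1
    )


def _recover_pdms_from_model(model: EncoderModel, x_bar: np.ndarray) -> tuple:
    """Kernel triple (k0, k1, k2) of a trained encoder at the data mean."""
    state = derivatives_at(model, x_bar)
    return state.f, state.J, state.H


def benchmark_recovery(
    n_sims: int = 100,
    stimulus_kind: str = "smooth",
    methods: tuple[str, ...] = ("mine", "ols", "ridge(1e2)", "ridge(1e4)"),
    T: int = 3600,
    n_epochs: int = 100,
    preset: str = "a",
    seed: int = 0,
) -> pd.DataFrame:
    """Receptive-field recovery comparison: encoder vs direct Volterra fits.

    Per simulation, a fresh stimulus drives the LN-LN system; each method
    fits the first two-thirds of the data, PDMs are extracted from its kernel
    estimates and matched (|cosine similarity|) against the planted filters;
    predictive power is scored on the held-out last third.
    """
    system = LNLNSystem.preset(preset)
    history_n = system.f_linear.shape[0]
    truth = np.vstack(
        [
            filter_to_window_layout(system.f_linear),
            filter_to_window_layout(system.f_nonlinear),
        ]
    )
    rows = []
    ss = np.random.SeedSequence(seed)
    for sim, child in zip(range(n_sims), ss.spawn(n_sims)):
        sim_seed = int(child.generate_state(1)[0] % (2 ** 31))
        stimulus, response = simulate_lnln(
            system, stimulus_kind, T=T, seed=sim_seed
        )
        s = standardize(stimulus)
        r = standardize(response)
        windows = make_windows(s[None, :], history_n)
        y = r[windows.t_index]
        n_train = int(round(windows.n_windows * 2.0 / 3.0))
        for method in methods:
            if method == "mine":
                model = EncoderModel(1, history_n, seed=sim_seed + 1)
                train_encoder(model, windows, y, n_epochs=n_epochs, seed=sim_seed + 2)
                x_bar = windows.flat[:n_train].mean(axis=0)
                k0, k1, k2 = _recover_pdms_from_model(model, x_bar)
                pdms = build_q_matrix(k0, k1, k2, provenance="taylor")
                yhat_val = model.predict(windows.flat[n_train:])
                val_corr = pearson_r(yhat_val, y[n_train:])
            else:
                alpha = 0.0 if method == "ols" else float(method[6:-1])
                # the Volterra design drops the first `memory` samples; align
                design = build_design(s, memory=history_n - 1)
                resp = r[design.t_index]
                nt = int(round(resp.shape[0] * 2.0 / 3.0))
                train_design = build_design(s[: nt + history_n - 1], memory=history_n - 1)
                est = fit_volterra(
                    train_design, resp[:nt],
                    method="ols" if method == "ols" else "ridge", alpha=alpha,
                )
                # k1/k2 indices are lags; flip into window layout for matching
                k1_w = est.k1[::-1]
                k2_w = est.k2[::-1, ::-1]
                pdms = build_q_matrix(est.k0, k1_w, k2_w, provenance="volterra")
                yhat_val = est.predict(design)[nt:]
                val_corr = pearson_r(yhat_val, resp[nt:])
            cs_lin, cs_non = match_pdms(pdms, truth)
            rows.append(
                {
                    "sim": sim,
                    "method": method,
                    "cs_linear": cs_lin,
                    "cs_nonlinear": cs_non,
                    "val_corr": val_corr,
                }
            )
    return pd.DataFrame(rows)
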