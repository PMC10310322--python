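"""Batch orchestration: fit every neuron, gate metric computation, persist.

`Mine.analyze_data` mirrors the published programmatic interface: it takes a
list of predictor traces and an ``(n_neurons, T)`` activity matrix, trains one
encoder per neuron on the temporally first ``train_fraction`` of the data and,
for neurons whose test correlation reaches ``corr_cut``, computes the gated
metrics (Taylor scores with bootstrap SEs, linear/second-order approximation
scores, receptive fields, optional Hessians).  Results round-trip losslessly
through HDF5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .data import is_standardized, make_windows
from .encoder import EncoderModel, train_encoder
from .errors import TrainingError
from .taylor import approximation_scores, bootstrap_taylor, taylor_metric

logger = logging.getLogger("mine")

__all__ = ["Mine", "MineData", "load_result"]


@dataclass
class MineData:
    """Per-neuron results of a batch analysis.

    Metric arrays are populated only for neurons whose test correlation
    reaches the fit cutoff; other rows hold NaN.  ``taylor_scores[:, c, 0]``
    is the mean Taylor metric of component ``c`` (predictors first, then
    pairwise interactions in lexicographic order) and ``[:, c, 1]`` its
    bootstrap SE.  ``jacobians`` holds the receptive fields (gradient at the
    training-data mean) of fit neurons; ``fit_neurons`` maps its rows back to
    neuron indices.
    """

    predictor_names: list[str]
    component_names: list[str]
    corr_cut: float
    correlations_trained: np.ndarray
    correlations_test: np.ndarray
    taylor_scores: np.ndarray | None = None
    model_lin_approx_scores: np.ndarray | None = None
    mean_exp_scores: np.ndarray | None = None
    jacobians: np.ndarray | None = None
    hessians: np.ndarray | None = None
    fit_neurons: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_neurons(self) -> int:
        return self.correlations_test.shape[0]

    @property
    def fit_flags(self) -> np.ndarray:
        return self.correlations_test >= self.corr_cut

    def save_to_hdf5(self, store: h5py.File | h5py.Group, overwrite: bool = False) -> None:
        """Write all arrays into an HDF5 file or group.

        Refuses to clobber an existing result unless ``overwrite`` is set.
        """
        key = "mine_data"
        if key in store:
            if not overwrite:
                raise ValueError(f"group '{key}' exists and overwrite=False")
            del store[key]
        g = store.create_group(key)
        g.attrs["corr_cut"] = self.corr_cut
        g.attrs["predictor_names"] = [n.encode() for n in self.predictor_names]
        g.attrs["component_names"] = [n.encode() for n in self.component_names]
        g.create_dataset("correlations_trained", data=self.correlations_trained)
        g.create_dataset("correlations_test", data=self.correlations_test)
        g.create_dataset("fit_neurons", data=self.fit_neurons)
        for name in ("taylor_scores", "model_lin_approx_scores", "mean_exp_scores",
                     "jacobians", "hessians"):
            arr = getattr(self, name)
            if arr is not None:
                g.create_dataset(name, data=arr)


def load_result(store: h5py.File | h5py.Group) -> MineData:
    """Inverse of :meth:`MineData.save_to_hdf5` (bit-exact round trip)."""
    g = store["mine_data"]
    kwargs = {}
    for name in ("taylor_scores", "model_lin_approx_scores", "mean_exp_scores",
                 "jacobians", "hessians"):
        if name in g:
            kwargs[name] = g[name][()]
    def _names(key: str) -> list[str]:
        return [n.decode() if isinstance(n, bytes) else str(n) for n in g.attrs[key]]

    return MineData(
        predictor_names=_names("predictor_names"),
        component_names=_names("component_names"),
        corr_cut=float(g.attrs["corr_cut"]),
        correlations_trained=g["correlations_trained"][()],
        correlations_test=g["correlations_test"][()],
        fit_neurons=g["fit_neurons"][()],
        **kwargs,
    )


@dataclass
class Mine:
    """Configuration and entry point of the batch analysis.

    Defaults follow the published interface: 2/3 training fraction, 50-sample
    model history, 100 training epochs, Taylor expansions every 5 samples
    predicting 25 samples ahead.  ``corr_cut`` 0.5 suits single-cell data; a
    lenient 0.1 is appropriate for blended multi-neuron signals such as
    widefield components.
    """

    train_fraction: float = 2.0 / 3.0
    model_history: int = 50
    corr_cut: float = 0.5
    compute_taylor: bool = True
    return_jacobians: bool = True
    taylor_look_ahead: int = 25
    taylor_pred_every: int = 5
    return_hessians: bool = False
    n_epochs: int = 100
    n_boot: int = 1000
    taylor_threshold: float = 0.1
    taylor_alpha: float = 0.05
    l1_weight: float = 1e-3
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 256
    seed: int = 0
    model_weight_store: h5py.File | h5py.Group | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.model_history < 2:
            raise ValueError("model_history must be >= 2")

    # ------------------------------------------------------------------ batch
    def analyze_data(
        self,
        pred_data: list[np.ndarray],
        response_data: np.ndarray,
        predictor_names: list[str] | None = None,
    ) -> MineData:
        """Fit and characterize one encoder per neuron.

        ``pred_data`` is a list of length-T predictor traces; ``response_data``
        an ``(n_neurons, T)`` activity matrix.  Per-neuron seeds derive from
        the master seed and the neuron index, so results do not depend on
        processing order.  A warning (not an error) is emitted for inputs
        that are not z-scored.
        """
        values = np.vstack([np.asarray(p, float) for p in pred_data])
        responses = np.atleast_2d(np.asarray(response_data, float))
        if values.shape[1] != responses.shape[1]:
            raise ValueError(
                f"predictors have {values.shape[1]} samples but responses "
                f"have {responses.shape[1]}"
            )
        P = values.shape[0]
        names = predictor_names or [f"P{i}" for i in range(P)]
        for trace, what in [(v, f"predictor '{n}'") for v, n in zip(values, names)]:
            if not is_standardized(trace):
                warnings.warn(f"{what} is not z-scored", UserWarning, stacklevel=2)
        if not all(is_standardized(r) for r in responses):
            warnings.warn("response matrix is not z-scored", UserWarning, stacklevel=2)

        windows = make_windows(values, self.model_history)
        y_all = responses[:, windows.t_index]
        n_neurons = responses.shape[0]
        pairs = [(i, j) for i in range(P) for j in range(i + 1, P)]
        component_names = names + [f"{names[i]} x {names[j]}" for i, j in pairs]
        n_components = len(component_names)

        result = MineData(
            predictor_names=names,
            component_names=component_names,
            corr_cut=self.corr_cut,
            correlations_trained=np.full(n_neurons, np.nan),
            correlations_test=np.full(n_neurons, np.nan),
        )
        if self.compute_taylor:
            result.taylor_scores = np.full((n_neurons, n_components, 2), np.nan)
            result.model_lin_approx_scores = np.full(n_neurons, np.nan)
            result.mean_exp_scores = np.full(n_neurons, np.nan)
        D = windows.history_n * P
        jacs: list[np.ndarray] = []
        hessians: list[np.ndarray] = []
        fit_idx: list[int] = []

        n_train = int(round(windows.n_windows * self.train_fraction))
        x_bar_train = windows.flat[:n_train].mean(axis=0)

        for i in range(n_neurons):
            seed_i = int(
                np.random.SeedSequence(self.seed, spawn_key=(i,)).generate_state(1)[0]
                % (2 ** 31)
            )
            model = EncoderModel(
                P, self.model_history, l1_weight=self.l1_weight,
                dropout_rate=self.dropout_rate, seed=seed_i,
            )
            try:
                fit = train_encoder(
                    model, windows, y_all[i], n_epochs=self.n_epochs,
                    train_fraction=self.train_fraction, batch_size=self.batch_size,
                    learning_rate=self.learning_rate, corr_cut=self.corr_cut,
                    seed=seed_i + 1,
                )
            except TrainingError as exc:
                logger.warning("neuron %d: training failed (%s); marked unfit", i, exc)
                continue
            result.correlations_trained[i] = fit.train_corr
            result.correlations_test[i] = fit.test_corr
            logger.info(
                "neuron %d/%d: train r=%.3f test r=%.3f%s",
                i + 1, n_neurons, fit.train_corr, fit.test_corr,
                "" if fit.fit_flag else " (below corr_cut)",
            )
            if self.model_weight_store is not None:
                self._store_weights(model, i)
            if not fit.fit_flag:
                continue
            fit_idx.append(i)
            if self.compute_taylor:
                scores = approximation_scores(
                    model, windows, stride=self.taylor_pred_every, x_bar=x_bar_train
                )
                result.model_lin_approx_scores[i] = scores.las
                result.mean_exp_scores[i] = scores.sos
                report = taylor_metric(
                    model, windows, names,
                    look_ahead=self.taylor_look_ahead, stride=self.taylor_pred_every,
                )
                report = bootstrap_taylor(
                    report, n_boot=self.n_boot, threshold=self.taylor_threshold,
                    alpha=self.taylor_alpha, n_comparisons=n_neurons, seed=seed_i + 2,
                )
                means = np.concatenate([report.t_pred, report.t_inter])
                ses = np.concatenate([report.se_pred, report.se_inter])
                result.taylor_scores[i, :, 0] = means
                result.taylor_scores[i, :, 1] = ses
            if self.return_jacobians:
                jacs.append(model.input_gradient(x_bar_train[None, :])[0])
            if self.return_hessians:
                hessians.append(model.input_hessian(x_bar_train))

        result.fit_neurons = np.asarray(fit_idx, dtype=int)
        if self.return_jacobians:
            result.jacobians = np.vstack(jacs) if jacs else np.empty((0, D))
        if self.return_hessians:
            result.hessians = (
                np.stack(hessians) if hessians else np.empty((0, D, D))
            )
        return result

    # ---------------------------------------------------------------- weights
    def _store_weights(self, model: EncoderModel, neuron: int) -> None:
        g = self.model_weight_store.require_group(f"neuron_{neuron:06d}")
        for k, v in model.weights().items():
            if k in g:
                del g[k]
            g.create_dataset(k, data=v)
        g.attrs["n_predictors"] = model.n_predictors
        g.attrs["history_n"] = model.history_n

    @staticmethod
    def load_model(store: h5py.File | h5py.Group, neuron: int) -> EncoderModel:
        """Rebuild a trained encoder from a weight store."""
        g = store[f"neuron_{neuron:06d}"]
        model = EncoderModel(int(g.attrs["n_predictors"]), int(g.attrs["history_n"]))
        model.set_weights({k: g[k][()] for k in g.keys()})
        return model
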