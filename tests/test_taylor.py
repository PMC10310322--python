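"""Taylor machinery: derivatives, complexity scores, predictor attribution,
bootstrap significance, curvature and nonlinearity coefficient."""

import numpy as np
import pytest

from mine.data import make_windows
from mine.encoder import EncoderModel
from mine.errors import UndefinedScoreError
from mine.taylor import (
    ComplexityScores,
    approximation_scores,
    bootstrap_taylor,
    complexity_class,
    curvature_metric,
    derivatives_at,
    nlc,
    taylor_metric,
)

from conftest import AdditiveSaturatingModel, LinearModel, ProductModel, QuadraticModel


class TestDerivatives:
    def test_linear_model_gradient_constant_hessian_zero(self, oracle_rng):
        w = oracle_rng.standard_normal(12)
        state = derivatives_at(LinearModel(w, 0.5), oracle_rng.standard_normal(12))
        np.testing.assert_array_equal(state.J, w)
        assert np.all(state.H == 0)

    def test_encoder_gradient_matches_finite_differences(self, oracle_rng):
        model = EncoderModel(2, 10, seed=5)
        x = oracle_rng.standard_normal(20)
        state = derivatives_at(model, x)
        eps = 1e-5
        for i in range(20):
            e = np.zeros(20)
            e[i] = eps
            fd = (model.predict((x + e)[None])[0] - model.predict((x - e)[None])[0]) / (2 * eps)
            assert state.J[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_encoder_hessian_matches_finite_differences(self, oracle_rng):
        model = EncoderModel(1, 8, seed=6)
        x = oracle_rng.standard_normal(8)
        state = derivatives_at(model, x)
        eps = 1e-4
        for i, j in [(0, 0), (2, 5), (7, 1)]:
            ei = np.zeros(8); ei[i] = eps
            ej = np.zeros(8); ej[j] = eps
            fd = (
                model.predict((x + ei + ej)[None])[0]
                - model.predict((x + ei - ej)[None])[0]
                - model.predict((x - ei + ej)[None])[0]
                + model.predict((x - ei - ej)[None])[0]
            ) / (4 * eps**2)
            assert state.H[i, j] == pytest.approx(fd, rel=1e-3, abs=1e-6)

    def test_hessian_symmetric(self, oracle_rng):
        model = EncoderModel(2, 12, seed=7)
        state = derivatives_at(model, oracle_rng.standard_normal(24))
        np.testing.assert_allclose(state.H, state.H.T, atol=1e-12)

    def test_additive_model_has_zero_cross_block(self, oracle_rng):
        """A model that sums separate transforms of two predictors has no
        cross-predictor second derivatives."""
        # predictor blocks: even indices (a) and odd indices (b) of the window
        a = np.zeros(10); a[::2] = oracle_rng.standard_normal(5)
        b = np.zeros(10); b[1::2] = oracle_rng.standard_normal(5)
        state = derivatives_at(AdditiveSaturatingModel(a, b), oracle_rng.standard_normal(10))
        cross = state.H[::2][:, 1::2]
        np.testing.assert_allclose(cross, 0.0, atol=1e-12)


class TestApproximationScores:
    def test_linear_model_perfect_las(self, oracle_rng):
        w = oracle_rng.standard_normal(6)
        X = oracle_rng.standard_normal((500, 6))
        scores = approximation_scores(LinearModel(w), X, stride=1)
        assert scores.las == pytest.approx(1.0, abs=1e-10)
        assert scores.sos == pytest.approx(1.0, abs=1e-10)

    def test_quadratic_model_las_low_sos_perfect(self, oracle_rng):
        w = oracle_rng.standard_normal(6) / np.sqrt(6)
        X = oracle_rng.standard_normal((2000, 6))
        scores = approximation_scores(QuadraticModel(w), X, stride=1)
        assert scores.las < 0.2
        assert scores.sos == pytest.approx(1.0, abs=1e-8)

    def test_trained_linear_neuron_scores_high(self, linear_task):
        scores = approximation_scores(linear_task["model"], linear_task["windows"])
        assert scores.las > 0.95

    def test_constant_output_rejected(self):
        with pytest.raises(UndefinedScoreError):
            approximation_scores(LinearModel(np.zeros(4)), np.zeros((100, 4)), stride=1)


class TestComplexityClass:
    @pytest.mark.parametrize(
        "las,sos,expected",
        [(0.95, 0.99, 0), (0.5, 0.7, 1), (0.3, 0.3, 2), (0.8, 0.1, 0), (0.79, 0.5, 1)],
    )
    def test_threshold_rules(self, las, sos, expected):
        assert complexity_class(ComplexityScores(las=las, sos=sos)) == expected


def _window_direction(h, P, p):
    """Unit vector spread over the lags of predictor p in a flattened window."""
    v = np.zeros(h * P)
    v[np.arange(h) * P + p] = 1.0
    return v / np.linalg.norm(v)


class TestTaylorMetric:
    @pytest.fixture(scope="class")
    def two_pred_windows(self):
        rng = np.random.default_rng(17)
        values = rng.standard_normal((2, 800))
        return make_windows(values, 10)

    def test_single_driver_attribution(self, two_pred_windows):
        """A model reading only predictor 0 yields T ~ 1 for it, ~0 elsewhere."""
        w = _window_direction(10, 2, 0)
        report = taylor_metric(
            LinearModel(w), two_pred_windows, ["A", "B"], look_ahead=5, stride=3
        )
        assert report.t_pred[0] > 0.9
        assert abs(report.t_pred[1]) < 1e-6
        assert report.r2_full == pytest.approx(1.0, abs=1e-10)

    def test_product_model_flags_interaction(self, two_pred_windows):
        a = _window_direction(10, 2, 0)
        b = _window_direction(10, 2, 1)
        report = taylor_metric(
            ProductModel(a, b), two_pred_windows, ["A", "B"], look_ahead=5, stride=3
        )
        assert report.t_pred[0] > 0.1
        assert report.t_pred[1] > 0.1
        assert report.t_inter[0] > 0.05

    def test_empty_removal_is_zero(self, two_pred_windows):
        """Removing an all-zero contribution leaves the prediction unchanged,
        so the Taylor metric of a predictor the model ignores is exactly 0."""
        w = _window_direction(10, 2, 0)
        report = taylor_metric(
            LinearModel(w), two_pred_windows, ["A", "B"], look_ahead=5, stride=3
        )
        np.testing.assert_array_equal(report.contrib_pred[1], 0.0)
        assert report.t_pred[1] == 0.0

    def test_too_few_points_rejected(self):
        rng = np.random.default_rng(0)
        windows = make_windows(rng.standard_normal((1, 80)), 10)
        with pytest.raises(ValueError):
            taylor_metric(LinearModel(np.ones(10)), windows, look_ahead=25, stride=5)


class TestBootstrap:
    def _report(self, n_time=800, seed=23):
        rng = np.random.default_rng(seed)
        windows = make_windows(rng.standard_normal((2, n_time)), 10)
        w = _window_direction(10, 2, 0)
        return taylor_metric(LinearModel(w), windows, ["A", "B"], look_ahead=5, stride=3)

    def test_nondriver_not_significant(self):
        report = bootstrap_taylor(self._report(), n_boot=200, seed=1)
        assert not report.sig_pred[1]
        assert report.sig_pred[0]

    def test_se_shrinks_with_expansion_points(self):
        """Bootstrap SEs scale roughly as 1/sqrt(number of expansion points)."""
        ses = []
        for n_time in (400, 3200):
            report = bootstrap_taylor(self._report(n_time=n_time), n_boot=300, seed=2)
            ses.append(report.se_pred[0])
        assert ses[1] < ses[0]

    def test_huge_threshold_never_significant(self):
        report = bootstrap_taylor(self._report(), n_boot=200, threshold=10.0, seed=3)
        assert not report.sig_pred.any()

    def test_n_boot_minimum_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_taylor(self._report(), n_boot=10)


class TestCurvatureAndNLC:
    def test_linear_model_zero_curvature(self, oracle_rng):
        w = oracle_rng.standard_normal(8)
        X = oracle_rng.standard_normal((200, 8))
        assert curvature_metric(LinearModel(w), X, stride=2) == 0.0

    def test_quadratic_curvature_hand_computed(self, oracle_rng):
        """For f = (w.x)^2 the Hessian is constant (2 w w^T), so the metric
        is the mean of ||2 w (w.u)|| over unit steps u."""
        w = oracle_rng.standard_normal(5)
        X = oracle_rng.standard_normal((120, 5))
        got = curvature_metric(QuadraticModel(w), X, stride=1)
        steps = X[1:] - X[:-1]
        units = steps / np.linalg.norm(steps, axis=1, keepdims=True)
        expected = np.mean(
            [np.linalg.norm(2 * np.outer(w, w) @ u) for u in units]
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_linear_model_nlc_one(self, oracle_rng):
        """On standardized uncorrelated data the linearized variance of a
        linear model equals its output variance, so NLC ~ 1."""
        w = oracle_rng.standard_normal(10)
        X = oracle_rng.standard_normal((4000, 10))
        assert nlc(LinearModel(w), X, stride=1) == pytest.approx(1.0, abs=0.1)

    def test_constant_model_nlc_undefined(self):
        with pytest.raises(UndefinedScoreError):
            nlc(LinearModel(np.zeros(4)), np.random.default_rng(0).standard_normal((50, 4)), stride=1)

    def test_nonlinearity_raises_both_metrics(self, oracle_rng):
        """A strongly curved model scores higher curvature and NLC than a
        linear model of matched scale."""
        w = oracle_rng.standard_normal(6) / np.sqrt(6)
        X = oracle_rng.standard_normal((800, 6))
        curv_lin = curvature_metric(LinearModel(w), X, stride=2)
        curv_quad = curvature_metric(QuadraticModel(w), X, stride=2)
        assert curv_quad > curv_lin
        assert nlc(QuadraticModel(w), X, stride=1) > 1.5


class TestMixtureLinearityResponse:
    """Downstream behavior of the linearity score on controlled mixtures."""

    def _las_for(self, response, stimulus, seed):
        from mine.data import make_windows, standardize
        from mine.encoder import EncoderModel, train_encoder

        windows = make_windows(standardize(stimulus)[None, :], 50)
        model = EncoderModel(1, 50, seed=seed)
        train_encoder(model, windows, response[windows.t_index], n_epochs=60,
                      seed=seed + 100)
        return approximation_scores(model, windows).las

    def test_nonlinear_mixture_degrades_las_monotonically(self):
        """Increasing the tanh-square-cube fraction drives the linearity
        score down monotonically (within sampling tolerance), far below the
        0.8 cutoff at full strength — while mixing in the *derivative* (a
        linear transform) leaves the score at ~1 despite decorrelating the
        response from the predictor."""
        from mine.synthetic import gen_mixture, gen_smooth_predictor

        x = gen_smooth_predictor(
            1650, seed=61, standardize_trace=False, amp_range=(1.0, 3.0)
        )
        fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
        las_nl = [
            self._las_for(gen_mixture(x, "tanh_sq_cube", f), x, seed=62 + i)
            for i, f in enumerate(fractions)
        ]
        assert las_nl[0] > 0.95
        assert las_nl[-1] < 0.8
        assert all(b <= a + 0.1 for a, b in zip(las_nl, las_nl[1:]))
        las_deriv = [
            self._las_for(gen_mixture(x, "derivative", f), x, seed=90 + i)
            for i, f in enumerate([0.0, 1.0])
        ]
        assert min(las_deriv) > 0.9
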