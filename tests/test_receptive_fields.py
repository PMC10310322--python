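"""Receptive-field extraction, PDM eigenanalysis, clustering, landscapes."""

import numpy as np
import pytest

from mine.data import make_windows, standardize
from mine.encoder import EncoderModel, train_encoder
from mine.receptive_fields import (
    build_q_matrix,
    cosine_similarity,
    extract_rf,
    greedy_cluster,
    landscape_similarity,
    match_pdms,
    response_landscape,
    spectral_cluster_cs,
)
from mine.synthetic import calcium_kernel, filter_to_window_layout, gen_smooth_predictor

from conftest import AdditiveSaturatingModel, LinearModel, ProductModel


class TestExtractRF:
    def test_rf_is_exactly_the_gradient(self, linear_task):
        model = linear_task["model"]
        x_bar = linear_task["windows"].flat.mean(axis=0)
        rfs = extract_rf(model, x_bar, ["S1"])
        J = model.input_gradient(x_bar[None, :])[0]
        np.testing.assert_array_equal(rfs.flat(), J)
        assert rfs.kernels.shape == (1, 50)

    def test_known_filter_recovery(self):
        """An encoder trained on a known-kernel convolution of a broadband
        stimulus recovers that kernel as its receptive field.  (Broadband
        input is required for identifiability: a band-limited stimulus leaves
        out-of-band filter components unconstrained.)"""
        T = 2500
        rng = np.random.default_rng(30)
        stim = standardize(rng.standard_normal(T))
        kernel = calcium_kernel(2.5, 0.2)
        resp = standardize(np.convolve(stim, kernel, mode="full")[:T])
        windows = make_windows(stim[None, :], 50)
        model = EncoderModel(1, 50, seed=35)
        fit = train_encoder(model, windows, resp[windows.t_index], n_epochs=60, seed=36)
        assert fit.test_corr > 0.9
        rfs = extract_rf(model, windows.flat.mean(axis=0), ["S1"])
        truth = filter_to_window_layout(kernel, 50)
        assert abs(cosine_similarity(rfs.kernel("S1"), truth)) > 0.95

    def test_nondriving_predictor_rf_near_zero(self):
        """With a second, irrelevant predictor the encoder's gradient energy
        concentrates on the driving one."""
        T = 2500
        rng = np.random.default_rng(31)
        s1 = standardize(rng.standard_normal(T))
        s2 = standardize(rng.standard_normal(T))
        kernel = calcium_kernel(2.5, 0.2)
        resp = standardize(np.convolve(s1, kernel, mode="full")[:T])
        windows = make_windows(np.vstack([s1, s2]), 50)
        model = EncoderModel(2, 50, seed=33)
        fit = train_encoder(model, windows, resp[windows.t_index], n_epochs=60, seed=34)
        assert fit.test_corr > 0.9
        rfs = extract_rf(model, windows.flat.mean(axis=0), ["S1", "S2"])
        assert np.linalg.norm(rfs.kernel("S2")) < 0.2 * np.linalg.norm(rfs.kernel("S1"))


class TestQMatrix:
    def test_rank_one_quadratic_pathway(self, oracle_rng):
        """k2 = f f^T with k1 = 0 plants f as the dominant mode."""
        f = oracle_rng.standard_normal(20)
        f /= np.linalg.norm(f)
        pdms = build_q_matrix(0.0, np.zeros(20), np.outer(f, f))
        assert abs(cosine_similarity(pdms.pdms(1)[0], f)) > 1 - 1e-10

    def test_pure_linear_kernel_block_eigenproblem(self, oracle_rng):
        """With k2 = 0 the eigenproblem reduces to the 2x2 block spanned by
        the constant direction and (0, w); a top mode lies in that span."""
        w = oracle_rng.standard_normal(15)
        pdms = build_q_matrix(0.0, w, np.zeros((15, 15)))
        top = pdms.pdms(2)
        best = max(abs(cosine_similarity(t, w)) for t in top)
        assert best > 1 - 1e-10

    def test_zero_kernels_zero_spectrum(self):
        pdms = build_q_matrix(0.0, np.zeros(5), np.zeros((5, 5)))
        np.testing.assert_allclose(pdms.eigenvalues, 0.0, atol=1e-14)

    def test_asymmetric_k2_rejected(self):
        k2 = np.zeros((4, 4))
        k2[0, 1] = 1.0
        with pytest.raises(ValueError):
            build_q_matrix(0.0, np.zeros(4), k2)


class TestMatchPDMs:
    def test_identical_and_flipped(self, oracle_rng):
        f = oracle_rng.standard_normal(10)
        f /= np.linalg.norm(f)
        pdms = build_q_matrix(0.0, np.zeros(10), np.outer(f, f))
        assert match_pdms(pdms, f[None, :])[0] == pytest.approx(1.0, abs=1e-10)
        assert match_pdms(pdms, -f[None, :])[0] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_filter_scores_zero(self, oracle_rng):
        f = np.zeros(10); f[0] = 1.0
        g = np.zeros(10); g[5] = 1.0
        pdms = build_q_matrix(0.0, np.zeros(10), np.outer(f, f))
        assert match_pdms(pdms, g[None, :], top_k=1)[0] == pytest.approx(0.0, abs=1e-10)

    def test_cosine_similarity_basics(self):
        assert cosine_similarity([1, 0], [0, 1]) == 0.0
        assert cosine_similarity([1, 1], [2, 2]) == pytest.approx(1.0)
        assert cosine_similarity([0, 0], [1, 1]) == 0.0


class TestGreedyCluster:
    def test_two_identical_one_orthogonal(self):
        rfs = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        out = greedy_cluster(rfs, cs_threshold=0.8)
        assert list(out.labels) == [0, 0, -1]

    def test_order_invariant_partition(self, oracle_rng):
        """Permuting the input order permutes labels but not the partition."""
        base = oracle_rng.standard_normal((3, 12))
        rfs = np.vstack([
            base[i] + 0.05 * oracle_rng.standard_normal(12)
            for i in (0, 0, 1, 1, 2, 2, 0, 1)
        ])
        out1 = greedy_cluster(rfs)
        perm = np.array([4, 2, 7, 0, 6, 1, 5, 3])
        out2 = greedy_cluster(rfs[perm])
        # compare the induced partitions as sets of frozensets
        def partition(labels, order):
            groups = {}
            for pos, lab in zip(order, labels):
                groups.setdefault(lab if lab >= 0 else f"s{pos}", set()).add(pos)
            return {frozenset(v) for v in groups.values()}
        assert partition(out1.labels, range(8)) == partition(out2.labels, perm)

    def test_planted_three_families(self, oracle_rng):
        """Receptive fields drawn from 3 well-separated noisy templates are
        recovered as exactly 3 clusters."""
        templates = np.linalg.qr(oracle_rng.standard_normal((20, 3)))[0].T
        rfs = np.vstack([
            t + 0.05 * oracle_rng.standard_normal(20)
            for t in templates for _ in range(6)
        ])
        out = greedy_cluster(rfs, cs_threshold=0.8)
        labels = out.labels.reshape(3, 6)
        assert (out.labels >= 0).all()
        assert len(np.unique(out.labels)) == 3
        for fam in labels:
            assert len(np.unique(fam)) == 1

    def test_needs_two_rfs(self):
        with pytest.raises(ValueError):
            greedy_cluster(np.ones((1, 4)))


class TestSpectralCluster:
    def test_block_diagonal_similarity(self):
        S = np.full((6, 6), -0.2)
        S[:3, :3] = 1.0
        S[3:, 3:] = 1.0
        labels = spectral_cluster_cs(S, 2, seed=0)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_planted_families_adjusted_rand(self, oracle_rng):
        from sklearn.metrics import adjusted_rand_score

        templates = np.linalg.qr(oracle_rng.standard_normal((20, 3)))[0].T
        rfs = np.vstack([
            t + 0.05 * oracle_rng.standard_normal(20)
            for t in templates for _ in range(8)
        ])
        norm = rfs / np.linalg.norm(rfs, axis=1, keepdims=True)
        S = norm @ norm.T
        labels = spectral_cluster_cs(S, 3, seed=0)
        truth = np.repeat([0, 1, 2], 8)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            spectral_cluster_cs(np.eye(3), 4)


class TestResponseLandscape:
    def test_additive_model_rows_are_shifts(self, oracle_rng):
        """Without interaction the landscape factorizes: every row differs
        from every other by a constant offset."""
        a = np.zeros(10); a[::2] = oracle_rng.standard_normal(5)
        b = np.zeros(10); b[1::2] = oracle_rng.standard_normal(5)
        model = AdditiveSaturatingModel(a / np.linalg.norm(a), b / np.linalg.norm(b))
        grid = np.linspace(-3, 3, 21)
        L = response_landscape(model, a, b, drives=grid)
        row_diffs = L - L[0]
        spread = row_diffs.std(axis=1)
        assert spread.max() < 1e-10

    def test_product_model_slope_scales_with_gate(self, oracle_rng):
        """For a multiplicative unit the response slope along one drive grows
        linearly with the other drive (gating)."""
        a = np.zeros(10); a[::2] = oracle_rng.standard_normal(5)
        b = np.zeros(10); b[1::2] = oracle_rng.standard_normal(5)
        model = ProductModel(a, b)
        grid = np.linspace(-3, 3, 13)
        L = response_landscape(model, a, b, drives=grid)
        slopes = np.gradient(L, grid, axis=1)[:, 6]
        fit = np.polyfit(grid, slopes, 1)
        assert abs(fit[0]) > 1e-6
        np.testing.assert_allclose(slopes, np.polyval(fit, grid), atol=1e-8)

    def test_zero_drive_returns_base_point_output(self, oracle_rng):
        a, b = np.eye(6)[0], np.eye(6)[3]
        model = LinearModel(oracle_rng.standard_normal(6), 0.7)
        grid = np.linspace(-5, 5, 11)
        L = response_landscape(model, a, b, drives=grid)
        assert L[5, 5] == pytest.approx(float(model.predict(np.zeros(6)[None])[0]))

    def test_landscape_similarity_self_maximal(self, oracle_rng):
        L1 = oracle_rng.standard_normal((16, 16))
        assert landscape_similarity(L1, L1) >= landscape_similarity(
            L1, oracle_rng.standard_normal((16, 16))
        )
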