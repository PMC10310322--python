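"""Receptive fields, principal dynamic modes, RF clustering, response landscapes.

The linear receptive field of a fitted neuron is the gradient of the encoder
at the data-mean input, reshaped per predictor and lag.  Nonlinear receptive
fields are recovered as principal dynamic modes (PDMs): eigenvectors of the
combined-kernel matrix Q built from the zeroth/first/second-order kernels
(the network's value, gradient and Hessian at the expansion point — or
directly fitted Volterra kernels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import SpectralClustering

from .data import WindowTensor

__all__ = [
    "ReceptiveFieldSet",
    "PDMSet",
    "RFClustering",
    "extract_rf",
    "build_q_matrix",
    "match_pdms",
    "cosine_similarity",
    "greedy_cluster",
    "spectral_cluster_cs",
    "response_landscape",
    "landscape_similarity",
]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two kernels (0 if either is null)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


# ------------------------------------------------------------ receptive fields
@dataclass
class ReceptiveFieldSet:
    """Per-predictor temporal kernels of one neuron.

    ``kernels[p, l]`` weights predictor ``p`` at lag position ``l`` (window
    layout: the last position is the present sample).  The concatenation of
    kernels in window order is exactly the gradient at the expansion point.
    """

    predictor_names: list[str]
    kernels: np.ndarray  # (P, history_n)
    neuron_id: int | None = None

    def flat(self) -> np.ndarray:
        """Back to flattened-window order (lag-major, predictor-minor)."""
        return self.kernels.T.reshape(-1)

    def kernel(self, name: str) -> np.ndarray:
        return self.kernels[self.predictor_names.index(name)]


def extract_rf(
    model,
    x_bar: np.ndarray,
    predictor_names: list[str] | None = None,
    neuron_id: int | None = None,
) -> ReceptiveFieldSet:
    """Linear receptive fields: the model gradient at the data-mean window."""
    x_bar = np.asarray(x_bar, float).ravel()
    J = model.input_gradient(x_bar[None, :])[0]
    P = model.n_predictors
    h = model.history_n
    if predictor_names is None:
        predictor_names = [f"P{i}" for i in range(P)]
    kernels = J.reshape(h, P).T
    return ReceptiveFieldSet(list(predictor_names), kernels, neuron_id)


# ---------------------------------------------------------------------- PDMs
@dataclass
class PDMSet:
    """Eigenstructure of the combined-kernel matrix Q.

    Eigenpairs are sorted by descending eigenvalue magnitude (symmetric
    nonlinearities can plant negative-eigenvalue modes, so ranking uses
    ``|lambda|``; signs are retained in ``eigenvalues``).  Candidate dynamic
    modes are the eigenvectors with the leading constant-term entry stripped
    and the remainder renormalized.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, aligned with eigenvalues
    provenance: str = "taylor"

    def pdms(self, n: int | None = None) -> np.ndarray:
        """Top candidate modes as rows, constant entry dropped, unit norm."""
        n = self.eigenvalues.shape[0] if n is None else n
        out = []
        for k in range(min(n, self.eigenvalues.shape[0])):
            v = self.eigenvectors[1:, k]
            nrm = np.linalg.norm(v)
            out.append(v / nrm if nrm > 0 else v)
        return np.vstack(out)


def build_q_matrix(
    k0: float,
    k1: np.ndarray,
    k2: np.ndarray,
    provenance: str = "taylor",
    sym_tol: float = 1e-6,
) -> PDMSet:
    """Assemble Q from the kernel triple and eigendecompose it.

    ``Q`` is the (n+1) x (n+1) symmetric matrix with ``k0`` in the corner,
    ``k1 / 2`` on the first row/column and ``k2`` as the trailing block.
    """
    k1 = np.asarray(k1, float).ravel()
    k2 = np.asarray(k2, float)
    n = k1.shape[0]
    if k2.shape != (n, n):
        raise ValueError(f"k2 must be {n}x{n}, got {k2.shape}")
    scale = max(np.abs(k2).max(), 1.0)
    if np.abs(k2 - k2.T).max() > sym_tol * scale:
        raise ValueError("k2 is not symmetric within tolerance")
    Q = np.empty((n + 1, n + 1))
    Q[0, 0] = k0
    Q[0, 1:] = 0.5 * k1
    Q[1:, 0] = 0.5 * k1
    Q[1:, 1:] = 0.5 * (k2 + k2.T)
    evals, evecs = np.linalg.eigh(Q)
    order = np.argsort(-np.abs(evals))
    return PDMSet(evals[order], evecs[:, order], provenance)


def match_pdms(
    pdm_set: PDMSet,
    truth_filters: np.ndarray,
    top_k: int | None = None,
) -> np.ndarray:
    """Best |cosine similarity| per planted filter among the top candidates.

    Defaults: the top 2 eigenvectors for Taylor-derived kernels, top 3 for
    directly fitted Volterra kernels (whose leading modes often include a
    constant-term component).
    """
    truth = np.atleast_2d(np.asarray(truth_filters, float))
    if top_k is None:
        top_k = 2 if pdm_set.provenance == "taylor" else 3
    if top_k < truth.shape[0]:
        raise ValueError("need at least as many candidates as planted filters")
    cands = pdm_set.pdms(top_k)
    return np.array(
        [max(abs(cosine_similarity(t, c)) for c in cands) for t in truth]
    )


# ------------------------------------------------------------------ clustering
@dataclass
class RFClustering:
    """Cluster labels per neuron (-1 = unclustered) and cluster mean kernels."""

    labels: np.ndarray
    means: np.ndarray  # (n_clusters, kernel_dim)
    method: str


def greedy_cluster(rf_list: np.ndarray, cs_threshold: float = 0.8) -> RFClustering:
    """Deterministic agglomerative clustering on cosine similarity.

    Repeatedly merges the pair (of receptive fields or running cluster means)
    with the highest cosine similarity, recomputing the cluster mean after
    each merge, until no pairwise similarity reaches ``cs_threshold``.  Items
    never merged are labelled -1.  Ties break on the lowest stable index, so
    the partition is independent of input order.
    """
    rfs = np.atleast_2d(np.asarray(rf_list, float))
    n = rfs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 receptive fields")
    # each active item: (sorted member tuple, running mean)
    items: list[tuple[tuple[int, ...], np.ndarray]] = [((i,), rfs[i]) for i in range(n)]
    while len(items) > 1:
        best, best_pair = -2.0, None
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                cs = cosine_similarity(items[a][1], items[b][1])
                if cs > best + 1e-15:
                    best, best_pair = cs, (a, b)
        if best < cs_threshold or best_pair is None:
            break
        a, b = best_pair
        members = tuple(sorted(items[a][0] + items[b][0]))
        mean = rfs[list(members)].mean(axis=0)
        items = [it for k, it in enumerate(items) if k not in (a, b)]
        items.append((members, mean))
        items.sort(key=lambda it: it[0])  # stable order for deterministic ties
    labels = np.full(n, -1, dtype=int)
    means = []
    cluster_id = 0
    for members, mean in items:
        if len(members) == 1:
            continue
        labels[list(members)] = cluster_id
        means.append(mean)
        cluster_id += 1
    means_arr = np.vstack(means) if means else np.empty((0, rfs.shape[1]))
    return RFClustering(labels=labels, means=means_arr, method="greedy")


def spectral_cluster_cs(
    similarity: np.ndarray,
    k: int,
    seed: int = 0,
) -> np.ndarray:
    """Spectral clustering on a (symmetric) cosine-similarity matrix.

    Similarities in [-1, 1] are shifted to non-negative affinities
    ``(S + 1) / 2`` before clustering.  Degenerate all-equal similarity
    matrices yield an arbitrary balanced partition.
    """
    S = np.asarray(similarity, float)
    n = S.shape[0]
    if S.shape != (n, n) or np.abs(S - S.T).max() > 1e-8:
        raise ValueError("similarity must be a symmetric square matrix")
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}]")
    affinity = np.clip((S + 1.0) / 2.0, 0.0, None)
    model = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed, assign_labels="discretize"
    )
    return model.fit_predict(affinity)


# ------------------------------------------------------------------ landscapes
def response_landscape(
    model,
    rf_a: np.ndarray,
    rf_b: np.ndarray,
    drives: np.ndarray | None = None,
    x_base: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted responses over a grid of two receptive-field drives.

    The drive for an input is a scaled copy of the unit-normalized receptive
    field (the ideal stimulus for that predictor); the input at grid point
    ``(i, j)`` is ``x_base + drives[i] * rf_a + drives[j] * rf_b``.  Rows vary
    the first drive.  Additive neurons produce landscapes whose rows are
    vertical shifts of each other; gated (multiplicative) neurons show
    drive-dependent slopes.
    """
    if drives is None:
        drives = np.linspace(-5.0, 5.0, 64)
    a = np.asarray(rf_a, float).ravel()
    b = np.asarray(rf_b, float).ravel()
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    base = np.zeros_like(a) if x_base is None else np.asarray(x_base, float).ravel()
    g = np.asarray(drives, float)
    inputs = base[None, None, :] + g[:, None, None] * a + g[None, :, None] * b
    flat = inputs.reshape(-1, a.shape[0])
    return np.asarray(model.predict(flat), float).reshape(g.shape[0], g.shape[0])


def landscape_similarity(l1: np.ndarray, l2: np.ndarray) -> float:
    """Maximum of the normalized 2D cross-correlation of two landscapes.

    Using the cross-correlation maximum rather than a pointwise similarity
    groups landscapes by shape, tolerating misalignment.
    """
    from scipy.signal import correlate2d

    a = np.asarray(l1, float)
    b = np.asarray(l2, float)
    a = (a - a.mean()) / (a.std() * np.sqrt(a.size))
    b = (b - b.mean()) / (b.std() * np.sqrt(b.size))
    return float(correlate2d(a, b, mode="full").max())


def mean_window(windows: WindowTensor) -> np.ndarray:
    """Convenience: data-mean flattened window (the Taylor expansion point)."""
    return windows.flat.mean(axis=0)
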