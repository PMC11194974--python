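"""Spectral regression (SR) and kernel spectral regression (KSR).

The regression is guided by a k-nearest-neighbour affinity graph over the
training pulses: predictions should agree for beats that are close in the
graph, i.e. the learned responses should have a small graph-smoothness
objective  phi = sum_ij (yhat_i - yhat_j)^2 W_ij.

The model is built in three stages:

1. spectral embedding — the m smoothest non-trivial eigenvectors of the
   normalized graph Laplacian (small generalized eigenvalues of W y = λ D y);
2. out-of-sample map — ridge regression from the input features onto the
   embedding (linear for SR; RBF-kernel ridge for KSR, kernel
   R(x_i, x) = exp(-beta ||x_i - x||^2));
3. target map — ridge regression of the latencies on the embedding.

Stage 2 makes the embedding available for unseen pulses, stage 3 turns it
into latency predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import Ridge
from sklearn.neighbors import kneighbors_graph

from .base import PeakDetector

__all__ = ["AffinityGraph", "build_affinity", "SpectralRegression", "graph_smoothness"]


@dataclass
class AffinityGraph:
    """Symmetric non-negative k-NN affinity matrix (zero diagonal)."""

    W: np.ndarray
    k_neighbors: int
    kernel: str

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T):
            raise ValueError("W must be symmetric")
        if np.any(W < 0):
            raise ValueError("W must be non-negative")
        self.W = W

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)


def build_affinity(X: np.ndarray, k_neighbors: int = 7, kernel: str = "heat") -> AffinityGraph:
    """Symmetrized k-NN graph with binary or heat-kernel weights.

    Heat weights are exp(-d^2 / (2 s^2)) with s the median neighbour
    distance, a standard self-scaling choice.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n <= 1:
        raise ValueError("need more than one sample to build a graph")
    if not (0 < k_neighbors < n):
        raise ValueError("k_neighbors must be in (0, n)")
    if kernel not in ("heat", "binary"):
        raise ValueError(f"unknown affinity kernel {kernel!r}")
    D = kneighbors_graph(X, k_neighbors, mode="distance", include_self=False).toarray()
    conn = D > 0
    # duplicate rows give zero distance but are still neighbours
    C = kneighbors_graph(X, k_neighbors, mode="connectivity", include_self=False).toarray()
    conn = conn | (C > 0)
    if kernel == "binary":
        W = conn.astype(float)
    else:
        d = D[conn & (D > 0)]
        s = np.median(d) if d.size else 1.0
        s = max(s, 1e-12)
        W = np.where(conn, np.exp(-(D**2) / (2 * s**2)), 0.0)
    W = np.maximum(W, W.T)  # symmetrize
    np.fill_diagonal(W, 0.0)
    return AffinityGraph(W=W, k_neighbors=k_neighbors, kernel=kernel)


def graph_smoothness(yhat: np.ndarray, W: np.ndarray) -> float:
    """The graph objective  sum_ij (yhat_i - yhat_j)^2 W_ij  (summed over outputs)."""
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float).T).T
    total = 0.0
    for col in yhat.T:
        diff = col[:, None] - col[None, :]
        total += float(np.sum(diff**2 * W))
    return total


def _spectral_embedding(W: np.ndarray, m: int) -> np.ndarray:
    """m smoothest non-trivial generalized eigenvectors of (D - W) y = λ D y."""
    d = W.sum(axis=1)
    d = np.maximum(d, 1e-12)
    d_isqrt = 1.0 / np.sqrt(d)
    L_sym = np.eye(len(d)) - d_isqrt[:, None] * W * d_isqrt[None, :]
    L_sym = 0.5 * (L_sym + L_sym.T)
    vals, vecs = scipy.linalg.eigh(L_sym, subset_by_index=[0, min(m, len(d) - 1)])
    # drop the trivial constant eigenvector, undo the symmetric normalization
    E = d_isqrt[:, None] * vecs[:, 1:]
    # unit-norm columns for a well-conditioned stage-3 regression
    norms = np.linalg.norm(E, axis=0)
    return E / np.maximum(norms, 1e-12)


class SpectralRegression(PeakDetector):
    """SR (linear) / KSR (RBF-kernelized) peak-latency regressor.

    Parameters
    ----------
    alpha : ridge regularizer of the feature->embedding map.  Large alpha
        shrinks the map to zero, so predictions collapse to the training
        mean of the targets.
    k_neighbors, kernel : affinity-graph construction.
    n_components : embedding dimension m.
    kernelized : if True (KSR), the feature->embedding map is RBF kernel
        ridge with width ``beta``; if False (SR), plain ridge.
    target_alpha : (small) ridge regularizer of the embedding->target map.
    """

    def __init__(
        self,
        alpha: float = 1e-2,
        k_neighbors: int = 7,
        kernel: str = "heat",
        n_components: int = 48,
        kernelized: bool = False,
        beta: float = 1.0,
        target_alpha: float = 1e-8,
    ) -> None:
        super().__init__()
        self.alpha = alpha
        self.k_neighbors = k_neighbors
        self.kernel = kernel
        self.n_components = n_components
        self.kernelized = kernelized
        self.beta = beta
        self.target_alpha = target_alpha

    def _fit(self, X: np.ndarray, Y: np.ndarray) -> None:
        n = X.shape[0]
        k = min(self.k_neighbors, n - 1)
        m = min(self.n_components, n - 1)
        graph = build_affinity(X, k_neighbors=k, kernel=self.kernel)
        E = _spectral_embedding(graph.W, m)
        try:
            if self.kernelized:
                self._stage2 = KernelRidge(alpha=self.alpha, kernel="rbf", gamma=self.beta)
            else:
                self._stage2 = Ridge(alpha=self.alpha)
            self._stage2.fit(X, E)
            self._stage3 = Ridge(alpha=self.target_alpha)
            self._stage3.fit(E, Y)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guidance path
            raise np.linalg.LinAlgError(
                f"singular system while fitting spectral regression: {exc}; "
                "increase the regularizer alpha"
            ) from exc
        self.graph_ = graph
        self.embedding_ = E

    def _predict(self, X: np.ndarray) -> np.ndarray:
        E_hat = self._stage2.predict(X)
        return self._stage3.predict(E_hat)
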