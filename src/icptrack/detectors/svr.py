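"""Support vector regression with an RBF kernel, one machine per peak.

The epsilon-insensitive loss fits a tube of width epsilon around the data;
predictions are reconstructed from the stored support set alone:

    yhat(x) = sum_{s in SV} (alpha_s^+ - alpha_s^-) R(x_s, x) + b,
    R(x_s, x) = exp(-beta ||x_s - x||^2).

The sklearn SMO solver produces the dual; prediction here is computed from
the stored support vectors and dual coefficients directly so the model is
self-contained (and testable against a brute-force dual QP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVR

from .base import PeakDetector

__all__ = ["SVRModel", "SupportVectorDetector", "rbf_kernel_matrix"]


def rbf_kernel_matrix(A: np.ndarray, B: np.ndarray, beta: float) -> np.ndarray:
    return np.exp(-beta * cdist(np.atleast_2d(A), np.atleast_2d(B), "sqeuclidean"))


@dataclass
class SVRModel:
    """Stored parts of one fitted epsilon-SVR: enough to predict alone."""

    support_vectors: np.ndarray   # (n_sv, d)
    dual_coef: np.ndarray         # (n_sv,) = alpha^+ - alpha^-
    bias: float
    beta: float                   # RBF width
    epsilon: float
    C: float
    constant: float | None = None  # fallback when no support vectors remain

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.constant is not None:
            return np.full(X.shape[0], self.constant)
        K = rbf_kernel_matrix(X, self.support_vectors, self.beta)
        return K @ self.dual_coef + self.bias


class SupportVectorDetector(PeakDetector):
    """One RBF epsilon-SVR per peak latency."""

    def __init__(self, C: float = 1000.0, epsilon: float = 0.5, beta: float = 1.7e3, tol: float = 1e-6) -> None:
        super().__init__()
        self.C = C
        self.epsilon = epsilon
        self.beta = beta
        self.tol = tol

    def _fit(self, X: np.ndarray, Y: np.ndarray) -> None:
        self.models_: list[SVRModel] = []
        for j in range(Y.shape[1]):
            svr = SVR(kernel="rbf", gamma=self.beta, C=self.C, epsilon=self.epsilon, tol=self.tol)
            svr.fit(X, Y[:, j])
            if svr.support_vectors_.shape[0] == 0:
                warnings.warn(
                    "no support vectors retained (all targets inside the epsilon tube); "
                    "falling back to a constant model",
                    stacklevel=2,
                )
                model = SVRModel(
                    support_vectors=np.empty((0, X.shape[1])),
                    dual_coef=np.empty(0),
                    bias=float(np.mean(Y[:, j])),
                    beta=self.beta,
                    epsilon=self.epsilon,
                    C=self.C,
                    constant=float(np.mean(Y[:, j])),
                )
            else:
                model = SVRModel(
                    support_vectors=svr.support_vectors_.copy(),
                    dual_coef=svr.dual_coef_[0].copy(),
                    bias=float(svr.intercept_[0]),
                    beta=self.beta,
                    epsilon=self.epsilon,
                    C=self.C,
                )
            self.models_.append(model)

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.predict(X) for m in self.models_])
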