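"""Feed-forward neural-network latency regressor.

A small multilayer perceptron minimizing the sum-of-squared-errors
objective.  The optimizer contract is the objective, not a specific
algorithm: the default is the quasi-Newton lbfgs solver, which is reliable
for moderate-sized networks; adam is available for larger problems.
Features and targets are standardized internally.
"""

from __future__ import annotations

import numpy as np
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .base import PeakDetector

__all__ = ["NeuralNetworkDetector"]


class NeuralNetworkDetector(PeakDetector):
    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (32,),
        alpha: float = 1e-4,
        solver: str = "lbfgs",
        learning_rate_init: float = 1e-3,
        max_iter: int = 800,
        seed: int = 0,
    ) -> None:
        super().__init__()
        self.hidden_layer_sizes = tuple(hidden_layer_sizes)
        self.alpha = alpha
        self.solver = solver
        self.learning_rate_init = learning_rate_init
        self.max_iter = max_iter
        self.seed = seed

    def _fit(self, X: np.ndarray, Y: np.ndarray) -> None:
        self._xs = StandardScaler().fit(X)
        self._ys = StandardScaler().fit(Y)
        self._mlp = MLPRegressor(
            hidden_layer_sizes=self.hidden_layer_sizes,
            alpha=self.alpha,
            solver=self.solver,
            learning_rate_init=self.learning_rate_init,
            max_iter=self.max_iter,
            random_state=self.seed,
        )
        self._mlp.fit(self._xs.transform(X), np.squeeze(self._ys.transform(Y)))

    def _predict(self, X: np.ndarray) -> np.ndarray:
        P = self._mlp.predict(self._xs.transform(X))
        if P.ndim == 1:
            P = P[:, None]
        return self._ys.inverse_transform(P)
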