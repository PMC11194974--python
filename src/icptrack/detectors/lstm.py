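"""LSTM latency regressor for single beats.

The 400-sample pulse vector is consumed sequentially by an LSTM cell and
the final hidden state is regressed onto the three peak latencies.  To keep
the recurrence length tractable the 400 samples are fed in consecutive
chunks (default 16 samples per step, 25 steps); every sample still enters
the network, only the step granularity changes.  Inputs and targets are
standardized internally.
"""

from __future__ import annotations

import numpy as np

from .._lstm import LSTMCore
from .base import PeakDetector

__all__ = ["LSTMDetector"]


class LSTMDetector(PeakDetector):
    def __init__(
        self,
        hidden_size: int = 32,
        chunk: int = 16,
        epochs: int = 500,
        lr: float = 1e-2,
        seed: int = 0,
    ) -> None:
        super().__init__()
        self.hidden_size = hidden_size
        self.chunk = chunk
        self.epochs = epochs
        self.lr = lr
        self.seed = seed

    def _to_sequences(self, X: np.ndarray) -> np.ndarray:
        n, d = X.shape
        c = self.chunk
        pad = (-d) % c
        if pad:
            X = np.pad(X, ((0, 0), (0, pad)), mode="edge")
        return X.reshape(n, (d + pad) // c, c)

    def _fit(self, X: np.ndarray, Y: np.ndarray) -> None:
        self._x_mean = X.mean()
        self._x_sd = X.std() + 1e-12
        self._y_mean = Y.mean(axis=0)
        self._y_sd = Y.std(axis=0) + 1e-12
        Xs = self._to_sequences((X - self._x_mean) / self._x_sd)
        Ys = (Y - self._y_mean) / self._y_sd
        self._core = LSTMCore(self.chunk, self.hidden_size, Y.shape[1], seed=self.seed)
        self._history = self._core.fit(Xs, Ys, mode="last", epochs=self.epochs, lr=self.lr)

    def _predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self._to_sequences((X - self._x_mean) / self._x_sd)
        hs, _ = self._core.forward(Xs)
        P = self._core.readout(hs[:, -1])
        return P * self._y_sd + self._y_mean
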