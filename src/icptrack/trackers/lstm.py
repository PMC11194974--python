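"""LSTM sequence filtering of peak observations.

The tracker consumes the per-beat 6-vector (three latencies, three
elevations) of noisy peak observations and is trained, sequence-to-
sequence, to output the true peak positions — i.e. it learns a temporal
denoising filter.  On masked beats it free-runs: its own previous output is
fed back as the input, producing inferred values flagged
'inferred-from-prior'; that is what lets it bridge missing-data gaps.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .._lstm import LSTMCore, lstm_step
from ..types import N_PEAKS
from .kalman import TrackOutput

__all__ = ["LSTMTracker"]


class LSTMTracker:
    def __init__(
        self,
        hidden_size: int = 32,
        epochs: int = 500,
        lr: float = 5e-3,
        chunk_length: int = 60,
        seed: int = 0,
    ) -> None:
        self.hidden_size = hidden_size
        self.epochs = epochs
        self.lr = lr
        self.chunk_length = chunk_length
        self.seed = seed
        self._core: Optional[LSTMCore] = None

    @staticmethod
    def _stack(lat: np.ndarray, elev: np.ndarray) -> np.ndarray:
        return np.concatenate([np.atleast_2d(lat), np.atleast_2d(elev)], axis=1)

    def fit(
        self,
        obs_lat: np.ndarray,
        obs_elev: np.ndarray,
        true_lat: np.ndarray,
        true_elev: np.ndarray,
    ) -> "LSTMTracker":
        X = self._stack(obs_lat, obs_elev)
        Y = self._stack(true_lat, true_elev)
        ok = np.all(np.isfinite(X), axis=1) & np.all(np.isfinite(Y), axis=1)
        X, Y = X[ok], Y[ok]
        self._mean = X.mean(axis=0)
        self._sd = X.std(axis=0) + 1e-12
        Xn = (X - self._mean) / self._sd
        Yn = (Y - self._mean) / self._sd
        # overlapping chunks keep BPTT length moderate
        L = min(self.chunk_length, Xn.shape[0])
        starts = list(range(0, Xn.shape[0] - L + 1, max(L // 2, 1)))
        Xc = np.stack([Xn[s : s + L] for s in starts])
        Yc = np.stack([Yn[s : s + L] for s in starts])
        self._core = LSTMCore(2 * N_PEAKS, self.hidden_size, 2 * N_PEAKS, seed=self.seed)
        self._history = self._core.fit(Xc, Yc, mode="seq", epochs=self.epochs, lr=self.lr)
        return self

    def track(
        self,
        obs_lat: np.ndarray,
        obs_elev: np.ndarray,
        mask: Optional[np.ndarray] = None,
    ) -> TrackOutput:
        """Filter a sequence; masked beats are free-run on own predictions."""
        if self._core is None:
            raise RuntimeError("tracker is not fitted")
        X = self._stack(obs_lat, obs_elev)
        n = X.shape[0]
        if mask is None:
            mask = np.all(np.isfinite(X), axis=1)
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("all beats are masked: nothing to track from")
        H = self._core.n_hidden
        h = np.zeros((1, H))
        c = np.zeros((1, H))
        out = np.empty((n, 2 * N_PEAKS))
        prev_pred: Optional[np.ndarray] = None
        for t in range(n):
            if mask[t]:
                x = (X[t] - self._mean) / self._sd
            elif prev_pred is not None:
                x = prev_pred  # free-run on the model's own output
            else:
                x = np.zeros(2 * N_PEAKS)
            h, c, _ = lstm_step(x[None, :], h, c, self._core.W, self._core.b)
            pred = (h @ self._core.Wout + self._core.bout)[0]
            prev_pred = pred
            out[t] = pred * self._sd + self._mean
        source = np.where(mask, "observed", "inferred-from-prior")
        return TrackOutput(
            latencies_ms=out[:, :N_PEAKS],
            elevations=out[:, N_PEAKS:],
            source=source,
        )
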