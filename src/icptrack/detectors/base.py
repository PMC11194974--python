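"""Common surface for single-pulse peak-latency regressors.

Every detector maps a preprocessed 400-sample pulse vector to the three peak
latencies in ms (original beat time).  Elevations are not regressed: they
are read off the waveform at the predicted latencies, which keeps the two
coordinates consistent by construction.

Training rows with a missing peak are excluded only for that peak's target:
when the target matrix contains NaN, the detector transparently fits one
sub-model per peak on that peak's finite rows.
"""

from __future__ import annotations

import copy
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from ..types import N_PEAKS, Pulse

__all__ = ["PeakDetector", "DetectorOutput", "predict_peaks"]


@dataclass
class DetectorOutput:
    """Predicted peak triple for one beat."""

    latencies_ms: np.ndarray      # (3,) sorted ascending
    elevations: np.ndarray        # (3,) waveform values at the latencies
    reordered: bool = False       # True when the ordering projection had to sort


class PeakDetector(ABC):
    """Base regressor: fit(X, Y) / predict(X) with per-target NaN handling."""

    def __init__(self) -> None:
        self._per_target: list | None = None
        self._fitted = False
        self._n_features: int | None = None

    @abstractmethod
    def _fit(self, X: np.ndarray, Y: np.ndarray) -> None:
        """Fit on fully finite X (n, d), Y (n, m)."""

    @abstractmethod
    def _predict(self, X: np.ndarray) -> np.ndarray:
        """Predict (n, m) for the multi-output model fitted by :meth:`_fit`."""

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "PeakDetector":
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and Y row counts differ")
        self._n_features = X.shape[1]
        if np.isfinite(Y).all():
            self._per_target = None
            self._fit(X, Y)
        else:
            self._per_target = []
            for j in range(Y.shape[1]):
                ok = np.isfinite(Y[:, j])
                if ok.sum() < 2:
                    raise ValueError(f"target {j} has fewer than 2 finite training rows")
                sub = copy.deepcopy(self)
                sub._per_target = None
                sub._fit(X[ok], Y[ok, j : j + 1])
                self._per_target.append(sub)
        self._fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("detector is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self._n_features:
            raise ValueError(
                f"feature length {X.shape[1]} does not match training length {self._n_features}"
            )
        if self._per_target is None:
            P = self._predict(X)
            return P[:, None] if P.ndim == 1 else P
        cols = [np.ravel(sub._predict(X)) for sub in self._per_target]
        return np.column_stack(cols)


def predict_peaks(model: PeakDetector, features: np.ndarray, pulse: Pulse) -> DetectorOutput:
    """Predict the peak triple for one beat.

    ``features`` is the beat's preprocessed vector (matching training) and
    ``pulse`` the original (pre-normalization) waveform from which elevations
    are interpolated.  Predicted latencies are clipped to the beat and
    projected onto the ordering constraint l1 < l2 < l3 by sorting; the
    ``reordered`` flag records when that projection changed anything.
    """
    lat = model.predict(np.asarray(features, dtype=float)[None, :])[0]
    if lat.size != N_PEAKS:
        raise ValueError("detector does not predict three latencies")
    lat = np.clip(lat, 0.0, pulse.duration_ms)
    reordered = bool(np.any(np.diff(lat) < 0))
    lat = np.sort(lat)
    elev = pulse.value_at(lat)
    return DetectorOutput(latencies_ms=lat, elevations=np.asarray(elev), reordered=reordered)
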