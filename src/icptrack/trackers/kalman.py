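"""Kalman filtering of peak latency/elevation across beats.

Each peak is tracked by an independent linear-Gaussian filter over the
4-dimensional state (latency, elevation, latency velocity, elevation
velocity) with a constant-velocity transition; there is no control input in
this application (B = 0, u = 0).  The recursion alternates prediction

    x^- = A x,   P^- = A P A' + Q

and measurement update with the standard gain

    K = P^- H' (H P^- H' + R)^{-1}
    x = x^- + K (z - H x^-),   P = (I - K H) P^-.

Process covariance defaults are estimated from the observation stream's
second differences; the measurement covariance should reflect the known or
estimated observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..types import N_PEAKS

__all__ = ["KalmanParams", "kalman_filter", "kalman_track", "TrackOutput", "default_kalman_params"]


@dataclass
class TrackOutput:
    """Per-beat filtered peak positions.

    ``source`` is 'observed' where an observation drove the update and
    'inferred-from-prior' where the value was produced without one.
    """

    latencies_ms: np.ndarray     # (n, 3)
    elevations: np.ndarray       # (n, 3)
    source: np.ndarray           # (n,) of {'observed', 'inferred-from-prior'}
    residuals: Optional[np.ndarray] = None   # innovation per beat where defined


def _check_psd(M: np.ndarray, name: str) -> None:
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.linalg.eigvalsh(M) < -1e-10):
        raise ValueError(f"{name} must be positive-semidefinite")


@dataclass
class KalmanParams:
    A: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    B: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        d = self.A.shape[0]
        m = self.H.shape[0]
        if self.A.shape != (d, d) or self.H.shape != (m, d):
            raise ValueError("inconsistent A/H dimensions")
        if self.Q.shape != (d, d) or self.R.shape != (m, m):
            raise ValueError("inconsistent Q/R dimensions")
        _check_psd(self.Q, "Q")
        _check_psd(self.R, "R")


def kalman_filter(
    zs: np.ndarray,
    params: KalmanParams,
    x0: Optional[np.ndarray] = None,
    P0: Optional[np.ndarray] = None,
    us: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the filter over observations ``zs`` (n, m); NaN rows are skipped
    (prediction only).  Returns (state estimates (n, d), covariances (n, d, d)).
    """
    A, H, Q, R, B = params.A, params.H, params.Q, params.R, params.B
    d = A.shape[0]
    zs = np.atleast_2d(np.asarray(zs, dtype=float))
    n = zs.shape[0]
    x = np.zeros(d) if x0 is None else np.asarray(x0, dtype=float).copy()
    P = np.eye(d) * 1e3 if P0 is None else np.asarray(P0, dtype=float).copy()
    xs = np.empty((n, d))
    Ps = np.empty((n, d, d))
    I = np.eye(d)
    for k in range(n):
        x = A @ x
        if B is not None and us is not None:
            x = x + B @ us[k]
        P = A @ P @ A.T + Q
        z = zs[k]
        if np.all(np.isfinite(z)):
            S = H @ P @ H.T + R
            K = P @ H.T @ np.linalg.inv(S)
            x = x + K @ (z - H @ x)
            P = (I - K @ H) @ P
        xs[k] = x
        Ps[k] = P
    return xs, Ps


def default_kalman_params(obs: np.ndarray, r_var: np.ndarray) -> KalmanParams:
    """Constant-velocity parameters for one peak's (latency, elevation) stream.

    ``obs`` is (n, 2); ``r_var`` the per-coordinate measurement noise
    variance.  The process (acceleration) variance is estimated from the
    observation second differences after subtracting the noise contribution:
    Var(DDz) = Var(DDx) + 6 R for iid measurement noise.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    r_var = np.broadcast_to(np.asarray(r_var, dtype=float), (2,))
    q = np.empty(2)
    for j in range(2):
        col = obs[np.isfinite(obs[:, j]), j]
        ddz = np.diff(col, n=2)
        v = np.var(ddz) - 6.0 * r_var[j] if ddz.size else 0.0
        q[j] = max(v, 1e-10)
    A = np.array(
        [[1, 0, 1, 0],
         [0, 1, 0, 1],
         [0, 0, 1, 0],
         [0, 0, 0, 1]], dtype=float)
    H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
    # acceleration noise enters position and velocity (discrete white-noise model)
    Q = np.zeros((4, 4))
    for j, qj in enumerate(q):
        Q[j, j] = qj / 4.0
        Q[j, j + 2] = Q[j + 2, j] = qj / 2.0
        Q[j + 2, j + 2] = qj
    R = np.diag(np.maximum(r_var, 1e-12))
    return KalmanParams(A=A, H=H, Q=Q, R=R)


def kalman_track(
    obs_lat: np.ndarray,
    obs_elev: np.ndarray,
    r_var_lat: float | np.ndarray = 1.0,
    r_var_elev: float | np.ndarray = 1e-4,
    params: Optional[list[KalmanParams]] = None,
) -> TrackOutput:
    """Track all three peaks through their noisy (latency, elevation) streams.

    Observations must be finite on unmasked beats; rows that are entirely
    NaN are treated as missing and raise, because the filter relies on its
    input for tracking (use the LSTM or MOCAIP trackers for missing-data
    inference).
    """
    obs_lat = np.atleast_2d(np.asarray(obs_lat, dtype=float))
    obs_elev = np.atleast_2d(np.asarray(obs_elev, dtype=float))
    n = obs_lat.shape[0]
    if np.any(~np.isfinite(obs_lat)) or np.any(~np.isfinite(obs_elev)):
        raise ValueError(
            "Kalman tracking requires observations at every beat; "
            "it cannot infer masked beats (no input, no update)"
        )
    r_lat = np.broadcast_to(np.asarray(r_var_lat, dtype=float), (N_PEAKS,))
    r_elev = np.broadcast_to(np.asarray(r_var_elev, dtype=float), (N_PEAKS,))
    lat_out = np.empty((n, N_PEAKS))
    elev_out = np.empty((n, N_PEAKS))
    for p in range(N_PEAKS):
        z = np.column_stack([obs_lat[:, p], obs_elev[:, p]])
        pars = params[p] if params is not None else default_kalman_params(z, np.array([r_lat[p], r_elev[p]]))
        x0 = np.array([z[0, 0], z[0, 1], 0.0, 0.0])
        P0 = np.diag([max(r_lat[p], 1e-6), max(r_elev[p], 1e-8), 1.0, 1e-2])
        xs, _ = kalman_filter(z, pars, x0=x0, P0=P0)
        lat_out[:, p] = xs[:, 0]
        elev_out[:, p] = xs[:, 1]
    source = np.array(["observed"] * n)
    resid = np.abs(lat_out - obs_lat)
    return TrackOutput(latencies_ms=lat_out, elevations=elev_out, source=source, residuals=resid)
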