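"""Nonparametric belief propagation (NBP) tracking of the three peaks.

Each beat contributes three graph nodes (p1, p2, p3) with hidden variable
h = (latency, elevation).  Edges: the intra-beat chain p1-p2-p3 carrying a
Gaussian compatibility potential on the inter-peak offset, and a temporal
edge from each peak to itself at the previous beat carrying a Gaussian
potential on the beat-to-beat increment.  The observation potential is a
Gaussian centred on the noisy observation.

Messages are represented nonparametrically as mixtures of D Gaussian
kernels.  A message from a to b is built by importance sampling: particles
are drawn from the product of a's observation potential and temporal prior
(a Gaussian mixture product, sampled exactly component-wise), reweighted by
the other incoming intra-beat messages, resampled back to D particles
(condensation), and propagated through the pairwise potential.  Beliefs are
the weighted particle estimates of  phi_a x temporal prior x incoming
messages; their means are reported per beat, i.e. the tracker runs as a
filter over the sequence.

With single-component Gaussian potentials and many particles the scheme
reduces to exact Gaussian belief propagation on the chain, which is the
oracle used by the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .._rng import substream
from ..types import N_PEAKS
from .kalman import TrackOutput

__all__ = ["NBPConfig", "nbp_track"]

_EDGES = [(0, 1), (1, 0), (1, 2), (2, 1)]  # directed intra-beat chain edges


@dataclass
class NBPConfig:
    """Potential parameters and sampling controls.

    obs_var         : (2,) observation potential variance (latency, elevation).
    spacing_mean    : (2, 2) mean offset h_b - h_a for edges (p1,p2), (p2,p3).
    spacing_var     : (2, 2) variance of those offsets.
    temporal_var    : (2,) variance of the beat-to-beat increment.
    n_particles     : D, kernels per message (>= 10).
    n_iterations    : BP sweeps per beat (>= 1; 2 is exact on a 3-chain).
    """

    obs_var: np.ndarray
    spacing_mean: np.ndarray
    spacing_var: np.ndarray
    temporal_var: np.ndarray
    n_particles: int = 75
    n_iterations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.obs_var = np.broadcast_to(np.asarray(self.obs_var, float), (2,)).copy()
        self.spacing_mean = np.asarray(self.spacing_mean, float).reshape(2, 2)
        self.spacing_var = np.asarray(self.spacing_var, float).reshape(2, 2)
        self.temporal_var = np.broadcast_to(np.asarray(self.temporal_var, float), (2,)).copy()
        if self.n_particles < 10:
            raise ValueError("need at least 10 particles")
        if self.n_iterations < 1:
            raise ValueError("need at least 1 BP iteration")
        for name in ("obs_var", "spacing_var", "temporal_var"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_annotations(
        cls,
        lat: np.ndarray,
        elev: np.ndarray,
        obs_var: float | np.ndarray = 1.0,
        n_particles: int = 75,
        n_iterations: int = 2,
        seed: int = 0,
    ) -> "NBPConfig":
        """Estimate compatibility potentials from training annotations."""
        lat = np.atleast_2d(np.asarray(lat, float))
        elev = np.atleast_2d(np.asarray(elev, float))
        sp_mean = np.empty((2, 2))
        sp_var = np.empty((2, 2))
        for e, (a, b) in enumerate([(0, 1), (1, 2)]):
            dl = lat[:, b] - lat[:, a]
            de = elev[:, b] - elev[:, a]
            sp_mean[e] = [np.nanmean(dl), np.nanmean(de)]
            sp_var[e] = [max(np.nanvar(dl), 1e-6), max(np.nanvar(de), 1e-8)]
        inc_l = np.nanvar(np.diff(lat, axis=0))
        inc_e = np.nanvar(np.diff(elev, axis=0))
        temporal = np.array([max(inc_l, 1e-6), max(inc_e, 1e-8)])
        ov = np.broadcast_to(np.asarray(obs_var, float), (2,)).copy()
        ov = np.maximum(ov, [1e-9, 1e-12])
        return cls(
            obs_var=ov,
            spacing_mean=sp_mean,
            spacing_var=sp_var,
            temporal_var=temporal,
            n_particles=n_particles,
            n_iterations=n_iterations,
            seed=seed,
        )


def _mixture_logpdf(x: np.ndarray, means: np.ndarray, var: np.ndarray, logw: np.ndarray) -> np.ndarray:
    """log of sum_i w_i N(x; mu_i, diag(var)) for x (P, 2), means (D, 2)."""
    d2 = (x[:, None, :] - means[None, :, :]) ** 2 / var[None, None, :]
    logk = -0.5 * d2.sum(axis=2) - 0.5 * np.log(2 * np.pi * var).sum()
    logk = logk + logw[None, :]
    m = logk.max(axis=1)
    return m + np.log(np.exp(logk - m[:, None]).sum(axis=1))


def _sample_gaussian_product_mixture(
    rng: np.random.Generator,
    mix_means: np.ndarray,
    mix_var: np.ndarray,
    mix_logw: np.ndarray,
    g_mean: np.ndarray,
    g_var: np.ndarray,
    n: int,
) -> np.ndarray:
    """Draw n samples from  N(g_mean, g_var) x mixture  (all diagonal).

    The product of a Gaussian with each mixture component is Gaussian with
    a computable weight, so the product mixture is sampled exactly.
    """
    tot_var = mix_var[None, :] + np.broadcast_to(g_var, (2,))[None, :]
    # component weight x integral of the pairwise product
    log_scale = (
        mix_logw
        - 0.5 * np.sum((mix_means - g_mean[None, :]) ** 2 / tot_var, axis=1)
        - 0.5 * np.log(tot_var).sum(axis=1)
    )
    log_scale -= log_scale.max()
    w = np.exp(log_scale)
    w /= w.sum()
    comp = rng.choice(len(w), size=n, p=w)
    prod_var = 1.0 / (1.0 / mix_var[None, :] + 1.0 / g_var[None, :])
    prod_mean = prod_var * (mix_means / mix_var[None, :] + g_mean[None, :] / g_var[None, :])
    return prod_mean[comp] + rng.normal(size=(n, 2)) * np.sqrt(prod_var)


def nbp_track(
    obs_lat: np.ndarray,
    obs_elev: np.ndarray,
    config: NBPConfig,
) -> TrackOutput:
    """Particle-based BP filtering over a sequence of peak observations."""
    obs_lat = np.atleast_2d(np.asarray(obs_lat, float))
    obs_elev = np.atleast_2d(np.asarray(obs_elev, float))
    if np.any(~np.isfinite(obs_lat)) or np.any(~np.isfinite(obs_elev)):
        raise ValueError(
            "NBP tracking requires observations at every beat; "
            "it cannot infer masked beats (no input, no update)"
        )
    n = obs_lat.shape[0]
    D = config.n_particles
    rng = substream(config.seed, "nbp")
    ov = config.obs_var

    # per-node temporal prior mixture (initialised flat around first obs)
    prior_means = [None] * N_PEAKS
    prior_var = [None] * N_PEAKS
    prior_logw = [None] * N_PEAKS

    lat_out = np.empty((n, N_PEAKS))
    elev_out = np.empty((n, N_PEAKS))

    def edge_params(a: int, b: int) -> tuple[np.ndarray, np.ndarray]:
        """Mean shift and variance for the message travelling a -> b."""
        if (a, b) in ((0, 1), (1, 2)):
            e = 0 if a == 0 else 1
            return config.spacing_mean[e], config.spacing_var[e]
        e = 0 if b == 0 else 1
        return -config.spacing_mean[e], config.spacing_var[e]

    for t in range(n):
        obs = np.column_stack([obs_lat[t], obs_elev[t]])  # (3, 2)
        # base distribution per node: obs potential x temporal prior
        base_samples = []
        for a in range(N_PEAKS):
            if prior_means[a] is None:
                s = obs[a][None, :] + rng.normal(size=(D, 2)) * np.sqrt(ov)[None, :]
            else:
                s = _sample_gaussian_product_mixture(
                    rng, prior_means[a], prior_var[a], prior_logw[a], obs[a], ov, D
                )
            base_samples.append(s)

        # intra-beat messages, iterated to convergence on the 3-chain
        msgs: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for _ in range(config.n_iterations):
            new_msgs = {}
            for a, b in _EDGES:
                pts = base_samples[a]
                logw = np.zeros(D)
                for c, dst in _EDGES:
                    if dst == a and c != b and (c, a) in msgs:
                        mm, mv, mw = msgs[(c, a)]
                        logw = logw + _mixture_logpdf(pts, mm, mv, mw)
                logw -= logw.max()
                w = np.exp(logw)
                if w.sum() <= 0 or not np.all(np.isfinite(w)):
                    w = np.ones(D)
                w /= w.sum()
                keep = rng.choice(D, size=D, p=w)  # condensation to D kernels
                shift, var = edge_params(a, b)
                new_msgs[(a, b)] = (pts[keep] + shift[None, :], var, np.full(D, -np.log(D)))
            msgs = new_msgs

        # beliefs: base x incoming messages, importance-weighted
        for a in range(N_PEAKS):
            pts = base_samples[a]
            logw = np.zeros(D)
            for c, dst in _EDGES:
                if dst == a and (c, a) in msgs:
                    mm, mv, mw = msgs[(c, a)]
                    logw = logw + _mixture_logpdf(pts, mm, mv, mw)
            logw -= logw.max()
            w = np.exp(logw)
            if w.sum() <= 0 or not np.all(np.isfinite(w)):
                w = np.ones(D)
            w /= w.sum()
            mean = (w[:, None] * pts).sum(axis=0)
            lat_out[t, a] = mean[0]
            elev_out[t, a] = mean[1]
            keep = rng.choice(D, size=D, p=w)
            bel = pts[keep]
            # next beat's temporal prior: belief kernels widened by the
            # temporal increment variance
            bw = np.maximum(bel.var(axis=0), 1e-12) * (4.0 / (3.0 * D)) ** 0.4  # Silverman
            prior_means[a] = bel
            prior_var[a] = bw + config.temporal_var
            prior_logw[a] = np.full(D, -np.log(D))

    source = np.array(["observed"] * n)
    resid = np.abs(lat_out - obs_lat)
    return TrackOutput(latencies_ms=lat_out, elevations=elev_out, source=source, residuals=resid)
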