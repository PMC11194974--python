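"""Generative simulator for triphasic ICP pulse sequences.

The shape of a single beat is modelled as a 3-component Gaussian mixture over
(latency, elevation): component k sits at latency l_k (fraction of the beat)
with temporal width sigma_k, and its elevation e_k scales the bump amplitude.
The rendered waveform on an n-sample grid is

    w(t) = sum_k  pi_k * (e_k + de_k) * exp(-(t - (l_k + dl_k))^2 / (2 sigma_k^2))

Slow physiological drift is emulated by two independent sine processes acting
on the latencies and elevations of every component (beat index as time), plus
optional small beat-to-beat jitter.  Uniform noise (a fraction of signal
range) and randomly placed missing segments of consecutive beats reproduce
monitoring artifacts.

Every generated beat carries exact groundtruth peak annotations (the local
maxima of the rendered waveform), which is what makes the simulator usable as
an evaluation harness with a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ._rng import substream
from .types import N_PEAKS, PeakAnnotation, Pulse, PulseSequence

__all__ = [
    "PulseGMM",
    "DynamicsConfig",
    "NoiseSpec",
    "MissingSpec",
    "render_pulse",
    "generate_sequence",
    "add_uniform_noise",
    "inject_missing",
    "fit_pulse_gmm",
    "sample_patient_model",
]


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass
class PulseGMM:
    """Gaussian-mixture pulse model.

    weights : (K,) mixture weights pi_k, summing to 1.
    means   : (K, 2) component means (l_k, e_k); latency as a fraction of the
              beat in (0, 1), elevation in normalized pressure units.
    widths  : (K,) temporal standard deviations sigma_k (fraction of beat).
    covariances : (K, 2, 2) full 2-D covariances, retained for prior models;
              the temporal marginal (``[0, 0]``) equals ``widths**2``.
    """

    weights: np.ndarray
    means: np.ndarray
    widths: np.ndarray
    covariances: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        K = self.K
        if self.means.shape != (K, 2) or self.widths.shape != (K,):
            raise ValueError("inconsistent GMM parameter shapes")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights <= 0):
            raise ValueError("mixture weights must be positive")
        lat = self.means[:, 0]
        if not (np.all(np.diff(lat) > 0) and lat[0] > 0 and lat[-1] < 1):
            raise ValueError("component latencies must satisfy 0 < l_1 < ... < l_K < 1")
        if np.any(self.widths <= 0):
            raise ValueError("temporal widths must be positive")
        if self.covariances is None:
            # default: diagonal, modest elevation variance
            cov = np.zeros((K, 2, 2))
            cov[:, 0, 0] = self.widths**2
            cov[:, 1, 1] = (0.05 * np.abs(self.means[:, 1]) + 1e-3) ** 2
            self.covariances = cov
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.shape != (K, 2, 2):
            raise ValueError("covariances must be (K, 2, 2)")
        for S in self.covariances:
            if not np.allclose(S, S.T):
                raise ValueError("covariances must be symmetric")
            if np.any(np.linalg.eigvalsh(S) <= 0):
                raise ValueError("covariances must be positive-definite")

    @property
    def K(self) -> int:
        return int(self.weights.size)

    @classmethod
    def default(cls) -> "PulseGMM":
        """Canonical triphasic beat: P1 sharpest and tallest, P3 broadest."""
        return cls(
            weights=np.array([0.35, 0.35, 0.30]),
            means=np.array([[0.13, 1.00], [0.33, 0.85], [0.55, 0.70]]),
            widths=np.array([0.045, 0.060, 0.075]),
        )


@dataclass
class DynamicsConfig:
    """Sinusoidal temporal dynamics of the mixture components.

    Two independent sine processes act on latency and elevation:

        dl_k(z) = A_l[k] * sin(2 pi z / T_l + phi_l)
        de_k(z) = A_e[k] * e_k * sin(2 pi z / T_e + phi_e)

    with beat index z as the time variable.  Elevation amplitudes are
    relative to the component elevation.  Small iid Gaussian jitter (clipped
    at 3 sd) adds beat-to-beat variability on top of the slow drift.
    """

    latency_amplitude: Union[float, np.ndarray] = 0.03
    elevation_amplitude: Union[float, np.ndarray] = 0.10
    latency_period: float = 60.0
    elevation_period: float = 97.0
    latency_phase: float = 0.0
    elevation_phase: float = 0.0
    latency_jitter_sd: float = 0.003
    elevation_jitter_sd: float = 0.02

    def amplitudes(self, K: int) -> tuple[np.ndarray, np.ndarray]:
        a_l = np.broadcast_to(np.asarray(self.latency_amplitude, dtype=float), (K,))
        a_e = np.broadcast_to(np.asarray(self.elevation_amplitude, dtype=float), (K,))
        if np.any(a_l < 0) or np.any(a_e < 0):
            raise ValueError("sine amplitudes must be non-negative")
        return a_l.copy(), a_e.copy()

    def validate_ordering(self, model: PulseGMM) -> None:
        """Latency excursions (sine + 3-sd jitter) must never reorder peaks."""
        a_l, _ = self.amplitudes(model.K)
        reach = a_l + 3.0 * self.latency_jitter_sd
        lat = model.means[:, 0]
        hi = lat[:-1] + reach[:-1]
        lo = lat[1:] - reach[1:]
        if np.any(hi >= lo):
            raise ValueError("latency dynamics would reorder mixture components")


@dataclass
class NoiseSpec:
    """Uniform additive noise at a fraction of signal range.

    level : fraction of the clean signal's range (0.05 = 5%).
    target: 'waveform_samples' perturbs every pressure sample;
            'peak_observations' perturbs latency and elevation streams
            independently, each scaled by its own range.
    """

    level: float
    target: str = "waveform_samples"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be non-negative")
        if self.target not in ("waveform_samples", "peak_observations"):
            raise ValueError(f"unknown noise target {self.target!r}")


@dataclass
class MissingSpec:
    """Randomly placed missing segments of consecutive beats.

    The sequence is divided into groups of ``group_size`` beats; each group
    receives ``segments_per_group`` (drawn from {2, 3} when None)
    non-overlapping missing segments of 2-4 consecutive beats.
    """

    group_size: int = 30
    segments_per_group: Optional[int] = None
    segment_length_range: tuple[int, int] = (2, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.segment_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid segment length range")
        if self.segments_per_group is not None and self.segments_per_group < 0:
            raise ValueError("segments_per_group must be >= 0")
        if self.segments_per_group != 0 and self.group_size <= 2 * hi:
            raise ValueError("group_size must exceed twice the max segment length")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _mixture_curve(model: PulseGMM, dl: np.ndarray, de: np.ndarray, frac: np.ndarray) -> np.ndarray:
    l = model.means[:, 0] + dl
    e = model.means[:, 1] + de
    amp = model.weights * e
    z = (frac[None, :] - l[:, None]) / model.widths[:, None]
    return (amp[:, None] * np.exp(-0.5 * z**2)).sum(axis=0)


#: Diastolic baseline of the rendered beat.  A real ICP beat starts at a
#: sharp end-diastolic minimum, rises steeply with the systolic upstroke and
#: decays slowly afterwards (the next beat truncates the decay), so the beat
#: onset is a robust alignment point.  The envelope
#:     S(t) = (1 - exp(-t / rise)) * exp(-t / decay)
#: scaled by ``amplitude`` reproduces that floor under the triphasic bumps.
BASELINE_AMPLITUDE = 0.15
BASELINE_RISE = 0.02
BASELINE_DECAY = 1.2


def _baseline_curve(frac: np.ndarray, amplitude: float = BASELINE_AMPLITUDE) -> np.ndarray:
    return amplitude * (1.0 - np.exp(-frac / BASELINE_RISE)) * np.exp(-frac / BASELINE_DECAY)


def render_pulse(
    model: PulseGMM,
    offsets: Optional[np.ndarray] = None,
    n_samples: int = 400,
    fs: float = 400.0,
    baseline: float = BASELINE_AMPLITUDE,
) -> tuple[Pulse, PeakAnnotation]:
    """Render one beat and its exact peak groundtruth.

    ``offsets`` is (K, 2): per-component (dl_k, de_k) shifts in latency
    fraction and elevation units; they must preserve component ordering.

    Groundtruth for peak k is the local maximum of the rendered waveform
    nearest to the (shifted) component centre, refined to sub-sample
    precision by a parabolic fit; when bump overlap suppresses the local
    maximum the component centre is used and flagged as a fallback.  The
    annotated elevation is the linear interpolation of the sampled waveform
    at the annotated latency, so annotation and waveform agree exactly under
    the package's interpolation convention.
    """
    if n_samples < 16:
        raise ValueError("n_samples must be at least 16")
    K = model.K
    if offsets is None:
        offsets = np.zeros((K, 2))
    offsets = np.asarray(offsets, dtype=float).reshape(K, 2)
    centers = model.means[:, 0] + offsets[:, 0]
    if not np.all(np.diff(centers) > 0):
        raise ValueError("offsets must preserve component ordering")

    frac = np.arange(n_samples) / n_samples
    w = _mixture_curve(model, offsets[:, 0], offsets[:, 1], frac) + _baseline_curve(frac, baseline)
    duration_ms = n_samples / fs * 1000.0

    # local maxima on the sample grid (interior points)
    interior = np.flatnonzero((w[1:-1] > w[:-2]) & (w[1:-1] >= w[2:])) + 1

    lat_ms = np.empty(K)
    fallback = np.zeros(K, dtype=bool)
    for k in range(K):
        if interior.size:
            m = interior[np.argmin(np.abs(frac[interior] - centers[k]))]
        else:
            m = -1
        if m < 0 or abs(frac[m] - centers[k]) > 2.5 * model.widths[k]:
            f_star = centers[k]
            fallback[k] = True
        else:
            # parabolic refinement through (m-1, m, m+1)
            y0, y1, y2 = w[m - 1], w[m], w[m + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -1.0, 1.0))
            f_star = frac[m] + delta / n_samples
        lat_ms[k] = f_star * duration_ms

    # groundtruth of nearby components may collapse to the same maximum only
    # under extreme overlap; ordering is enforced by the model invariants.
    t_grid = np.arange(n_samples) / fs * 1000.0
    elev = np.interp(lat_ms, t_grid, w)
    pulse = Pulse(samples=w, fs=fs)
    ann = PeakAnnotation(latencies_ms=lat_ms, elevations=elev, fallback=fallback)
    return pulse, ann


def generate_sequence(
    model: PulseGMM,
    dynamics: Optional[DynamicsConfig] = None,
    n_pulses: int = 300,
    fs: float = 400.0,
    n_samples: int = 400,
    seed: int = 0,
    patient_id: str = "sim",
    baseline: float = BASELINE_AMPLITUDE,
) -> PulseSequence:
    """Generate an ordered sequence of beats with sinusoidal peak dynamics."""
    if dynamics is None:
        dynamics = DynamicsConfig()
    dynamics.validate_ordering(model)
    K = model.K
    a_l, a_e = dynamics.amplitudes(K)
    rng = substream(seed, "dynamics")

    z = np.arange(n_pulses)
    sin_l = np.sin(2 * np.pi * z / dynamics.latency_period + dynamics.latency_phase)
    sin_e = np.sin(2 * np.pi * z / dynamics.elevation_period + dynamics.elevation_phase)

    jit_l = rng.normal(0.0, dynamics.latency_jitter_sd, size=(n_pulses, K))
    jit_e = rng.normal(0.0, dynamics.elevation_jitter_sd, size=(n_pulses, K))
    np.clip(jit_l, -3 * dynamics.latency_jitter_sd, 3 * dynamics.latency_jitter_sd, out=jit_l)
    np.clip(jit_e, -3 * dynamics.elevation_jitter_sd, 3 * dynamics.elevation_jitter_sd, out=jit_e)

    e_k = model.means[:, 1]
    pulses, anns = [], []
    for i in range(n_pulses):
        dl = a_l * sin_l[i] + jit_l[i]
        de = e_k * (a_e * sin_e[i] + jit_e[i])
        p, a = render_pulse(model, np.column_stack([dl, de]), n_samples=n_samples, fs=fs, baseline=baseline)
        pulses.append(p)
        anns.append(a)
    return PulseSequence(pulses=pulses, annotations=anns, patient_id=patient_id, fs=fs)


# ---------------------------------------------------------------------------
# noise and missing data
# ---------------------------------------------------------------------------


def _noisy_array(x: np.ndarray, level: float, rng: np.random.Generator, per_column: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot add noise to an empty input")
    out = x.copy()
    if level == 0:
        return out
    if per_column and x.ndim == 2:
        for j in range(x.shape[1]):
            col = x[:, j]
            fin = np.isfinite(col)
            a = level * (np.nanmax(col) - np.nanmin(col))
            out[fin, j] = col[fin] + rng.uniform(-a, a, size=int(fin.sum()))
    else:
        a = level * (np.nanmax(x) - np.nanmin(x))
        noise = rng.uniform(-a, a, size=x.shape)
        fin = np.isfinite(x)
        out[fin] = x[fin] + noise[fin]
    return out


def add_uniform_noise(x, spec: NoiseSpec):
    """Return a noisy copy of ``x``; the clean input is unchanged.

    Each perturbed value v becomes v + U(-a, a) with a = level x (range of
    the clean stream).  Accepts a plain array (waveform samples, range of the
    whole array, or per-column range for 2-D observation streams when
    ``spec.target == 'peak_observations'``), a Pulse (its own range), or a
    PulseSequence (per-pulse range; masked beats untouched, annotations keep
    the clean groundtruth).
    """
    rng = substream(spec.seed, "noise")
    if isinstance(x, PulseSequence):
        pulses = []
        for p in x.pulses:
            if p is None:
                pulses.append(None)
            else:
                pulses.append(Pulse(_noisy_array(p.samples, spec.level, rng, False), fs=p.fs))
        return PulseSequence(
            pulses=pulses,
            annotations=list(x.annotations),
            patient_id=x.patient_id,
            mask=x.mask.copy(),
            fs=x.fs,
        )
    if isinstance(x, Pulse):
        return Pulse(_noisy_array(x.samples, spec.level, rng, False), fs=x.fs)
    per_col = spec.target == "peak_observations"
    return _noisy_array(np.asarray(x), spec.level, rng, per_col)


def inject_missing(seq: PulseSequence, spec: MissingSpec) -> PulseSequence:
    """Mask randomly placed segments of consecutive beats in each group.

    Masked beats carry no waveform or annotation; the availability mask
    records them.  Per group the segment count is ``segments_per_group``
    (or drawn from {2, 3}), each segment 2-4 beats, non-overlapping.
    """
    n = len(seq)
    rng = substream(spec.seed, "missing")
    lo, hi = spec.segment_length_range
    mask = seq.mask.copy()

    for g_start in range(0, n, spec.group_size):
        g_end = min(g_start + spec.group_size, n)
        g_len = g_end - g_start
        n_seg = spec.segments_per_group
        if n_seg is None:
            n_seg = int(rng.integers(2, 4))
        if n_seg == 0:
            continue
        if g_len < n_seg * hi:
            if g_len < spec.group_size:  # short trailing group: skip
                continue
            raise ValueError(f"cannot place {n_seg} segments in group starting at beat {g_start}")
        placed = None
        for _ in range(500):
            lengths = rng.integers(lo, hi + 1, size=n_seg)
            starts = rng.integers(0, g_len - lengths + 1)
            order = np.argsort(starts)
            starts, lengths = starts[order], lengths[order]
            # a one-beat gap keeps segments (and groups) from merging into
            # longer missing runs than the spec'd segment lengths
            if np.any(starts[1:] < (starts[:-1] + lengths[:-1] + 1)):
                continue
            prev_end = np.flatnonzero(~mask[:g_start])
            if prev_end.size and g_start + starts[0] <= prev_end[-1] + 1:
                continue
            placed = (starts, lengths)
            break
        if placed is None:
            raise ValueError(f"infeasible missing-segment packing in group starting at beat {g_start}")
        for s, L in zip(*placed):
            mask[g_start + s : g_start + s + L] = False

    pulses = [p if m else None for p, m in zip(seq.pulses, mask)]
    anns = [a if m else None for a, m in zip(seq.annotations, mask)]
    return PulseSequence(pulses=pulses, annotations=anns, patient_id=seq.patient_id, mask=mask, fs=seq.fs)


# ---------------------------------------------------------------------------
# model fitting (weighted EM) and patient sampling
# ---------------------------------------------------------------------------


def _weighted_em_1d(
    t: np.ndarray, w: np.ndarray, K: int, rng: np.random.Generator,
    bg_density: Optional[np.ndarray] = None,
    max_iter: int = 500, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, float]:
    """EM for a 1-D K-component Gaussian mixture with sample weights w.

    ``bg_density`` optionally adds a fixed-shape background component (free
    weight only) that absorbs non-peak mass such as the diastolic floor.
    Returns (pi, mu, sigma, pi_background, converged, loglik).
    """
    w = w / w.sum()
    # deterministic quantile initialisation, small seeded perturbation
    cdf = np.cumsum(w)
    qs = (np.arange(K) + 0.5) / K
    mu = np.interp(qs, cdf, t) + rng.normal(0, 1e-4, size=K)
    var_t = np.sum(w * (t - np.sum(w * t)) ** 2)
    sig = np.full(K, np.sqrt(var_t) / K + 1e-4)
    use_bg = bg_density is not None
    pi0 = 0.2 if use_bg else 0.0
    pi = np.full(K, (1.0 - pi0) / K)
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        z = (t[:, None] - mu[None, :]) / sig[None, :]
        logp = -0.5 * z**2 - np.log(sig[None, :]) - 0.5 * np.log(2 * np.pi) + np.log(pi[None, :])
        if use_bg:
            with np.errstate(divide="ignore"):
                logp = np.column_stack([logp, np.log(pi0 * bg_density + 1e-300)])
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        s = p.sum(axis=1, keepdims=True)
        resp = p / s
        ll = float(np.sum(w * (np.log(s[:, 0]) + m[:, 0])))
        nk = (w[:, None] * resp).sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        if use_bg:
            pi0 = float(nk[K])
            nk = nk[:K]
            resp = resp[:, :K]
        mu = (w[:, None] * resp * t[:, None]).sum(axis=0) / nk
        var = (w[:, None] * resp * (t[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sig = np.sqrt(np.maximum(var, 1e-8))
        total = nk.sum() + pi0
        pi = nk / total
        pi0 = pi0 / total
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_prev = ll
    return pi, mu, sig, pi0, converged, ll


def fit_pulse_gmm(pulses, K: int = 3, seed: int = 0) -> PulseGMM:
    """Fit a K-component pulse mixture to a set of beats by weighted EM.

    Each beat is treated as a (pressure-weighted) density over beat time;
    EM recovers component latencies, temporal widths, and temporal mass
    fractions, which serve as the mixture weights.  Because a 1-D curve
    determines only the amplitude products pi_k * e_k, elevations are derived
    from fitted bump heights under this mass-fraction convention.

    Components are returned sorted by latency; the fit is deterministic for
    a given seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    mat = _pulses_to_matrix(pulses)
    n = mat.shape[0]
    if n < 10 * K:
        raise ValueError(f"need at least {10 * K} pulses to fit K={K} components")

    mean_pulse = mat.mean(axis=0)
    if np.any(mean_pulse < 0):
        mean_pulse = mean_pulse - mean_pulse.min()
    total = mean_pulse.sum()
    if total <= 0:
        raise ValueError("degenerate pulses: zero total pressure")
    ns = mean_pulse.size
    frac = np.arange(ns) / ns
    weights = mean_pulse / total

    # fixed-shape background absorbs the diastolic floor so EM sees peak mass
    bg = _baseline_curve(frac, 1.0)
    bg = bg / (bg.sum() / ns)

    rng = substream(seed, "gmm-fit")
    pi, mu, sig, pi0, converged, ll = _weighted_em_1d(frac, weights, K, rng, bg_density=bg)
    if not converged:
        raise RuntimeError(f"EM did not converge (last log-likelihood {ll:.6g})")
    order = np.argsort(mu)
    pi, mu, sig = pi[order], mu[order], sig[order]
    mu = np.clip(mu, 1e-4, 1 - 1e-4)

    # bump heights in the pulses' own pressure units (peak mass only)
    S = total / ns * (1.0 - pi0)  # integral of the mean pulse's peak mass
    pi = pi / pi.sum()
    heights = S * pi / (sig * np.sqrt(2 * np.pi))
    elev = heights / pi  # mass-fraction convention: pi_hat * e_hat = height

    # elevation spread across beats at each component centre
    idx = np.clip((mu * ns).astype(int), 0, ns - 1)
    elev_var = mat[:, idx].var(axis=0)
    cov = np.zeros((K, 2, 2))
    cov[:, 0, 0] = sig**2
    cov[:, 1, 1] = np.maximum(elev_var, 1e-8)
    return PulseGMM(weights=pi / pi.sum(), means=np.column_stack([mu, elev]), widths=sig, covariances=cov)


def _pulses_to_matrix(pulses) -> np.ndarray:
    if isinstance(pulses, np.ndarray):
        mat = np.atleast_2d(np.asarray(pulses, dtype=float))
    else:
        rows = [p.samples if isinstance(p, Pulse) else np.asarray(p, dtype=float) for p in pulses]
        lens = {r.size for r in rows}
        if len(lens) != 1:
            raise ValueError("all pulses must have the same length")
        mat = np.vstack(rows)
    if not np.all(np.isfinite(mat)):
        raise ValueError("pulses contain non-finite samples")
    return mat


def sample_patient_model(rng: np.random.Generator, base: Optional[PulseGMM] = None) -> PulseGMM:
    """Draw an independent patient-specific variant of the pulse model.

    Component latencies, elevations, widths and weights are jittered around
    the base model within ranges that keep the triphasic ordering and leave
    three resolvable bumps, emulating inter-patient morphology differences.
    """
    if base is None:
        base = PulseGMM.default()
    for _ in range(200):
        lat = base.means[:, 0] + rng.uniform(-0.02, 0.02, size=base.K)
        elev = base.means[:, 1] * rng.uniform(0.9, 1.1, size=base.K)
        widths = base.widths * rng.uniform(0.9, 1.1, size=base.K)
        w = base.weights * rng.uniform(0.85, 1.15, size=base.K)
        w = w / w.sum()
        if np.all(np.diff(lat) > 0.08) and lat[0] > 0.05 and lat[-1] < 0.9:
            try:
                return PulseGMM(weights=w, means=np.column_stack([lat, elev]), widths=widths)
            except ValueError:
                continue
    raise RuntimeError("could not sample a valid patient model")
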