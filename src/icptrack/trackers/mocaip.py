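"""MOCAIP-style peak designation: representative pulse, curvature
candidates, Gaussian-prior designation.

The Morphological Clustering and Analysis of ICP Pulse procedure detects
peaks in three steps: (1) hierarchical clustering of a window of consecutive
beats yields a noise-robust representative pulse; (2) candidate peaks are
extracted from the representative's second derivative (local maxima plus
inflections bordering the convex/concave regions of the ascending and
descending edges); (3) the ordered candidate triple maximizing the joint
likelihood under per-peak Gaussian-mixture priors over (latency, elevation)
is designated as (p1, p2, p3).

Because designation needs only a prior and a waveform window, the procedure
emits estimates even for masked beats inside a window, which is what makes
it usable in the missing-data experiment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist
from sklearn.mixture import GaussianMixture

from ..types import N_PEAKS, Pulse, PulseSequence
from .kalman import TrackOutput

__all__ = [
    "CandidateSet",
    "MocaipPrior",
    "mocaip_candidates",
    "mocaip_designate",
    "mocaip_representative_pulse",
    "mocaip_track",
]


@dataclass
class CandidateSet:
    """Curvature-derived candidate peaks, sorted by latency."""

    latencies_ms: np.ndarray
    elevations: np.ndarray
    regions: list[str]
    too_few: bool = False

    def __len__(self) -> int:
        return int(self.latencies_ms.size)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    w = np.hanning(window + 2)[1:-1]
    w /= w.sum()
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, w, mode="same")[pad : pad + x.size]


def mocaip_candidates(pulse: Pulse, smooth_window: int = 11) -> CandidateSet:
    """Candidate peaks from the second derivative of the smoothed pulse.

    Candidates are the interior local maxima of the smoothed waveform plus
    the inflection points (sign changes of the second derivative) that
    delimit the convex/concave regions of the ascending and descending
    edges.  A set with fewer than three candidates is returned as-is and
    flagged (designation may then fail or emit missing peaks).
    """
    y = _smooth(np.asarray(pulse.samples, float), smooth_window)
    n = y.size
    t_ms = np.arange(n) / pulse.fs * 1000.0
    d2 = np.gradient(np.gradient(y))

    apex = int(np.argmax(y))
    cand_idx: list[int] = []
    regions: list[str] = []

    # local maxima of the smoothed signal
    loc_max = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
    for m in loc_max:
        cand_idx.append(int(m))
        regions.append("max-ascending" if m <= apex else "max-descending")

    # inflections: sign changes of d2 with non-negligible curvature
    # absolute floor guards against pure float noise on flat/linear parts
    thresh = max(1e-6 * np.abs(d2).max(), 1e-10 * (np.ptp(y) + 1e-30))
    s = np.where(d2 > thresh, 1, np.where(d2 < -thresh, -1, 0))
    nz = np.flatnonzero(s != 0)
    for i, j in zip(nz[:-1], nz[1:]):
        if s[i] != s[j]:
            m = int((i + j) // 2)
            edge = "ascending" if m <= apex else "descending"
            kind = "convex-to-concave" if s[i] > 0 else "concave-to-convex"
            cand_idx.append(m)
            regions.append(f"{kind}-{edge}")

    order = np.argsort(cand_idx)
    idx_sorted: list[int] = []
    reg_sorted: list[str] = []
    for o in order:
        m = cand_idx[o]
        if idx_sorted and m - idx_sorted[-1] <= 2:  # dedup near-coincident
            continue
        idx_sorted.append(m)
        reg_sorted.append(regions[o])
    idx_arr = np.array(idx_sorted, dtype=int)
    return CandidateSet(
        latencies_ms=t_ms[idx_arr] if idx_arr.size else np.empty(0),
        elevations=y[idx_arr] if idx_arr.size else np.empty(0),
        regions=reg_sorted,
        too_few=len(idx_sorted) < N_PEAKS,
    )


@dataclass
class MocaipPrior:
    """Per-peak Gaussian-mixture priors over (latency ms, elevation)."""

    mixtures: list[GaussianMixture]

    @classmethod
    def fit(
        cls,
        latencies: np.ndarray,
        elevations: np.ndarray,
        n_components: int = 1,
        seed: int = 0,
    ) -> "MocaipPrior":
        latencies = np.atleast_2d(np.asarray(latencies, float))
        elevations = np.atleast_2d(np.asarray(elevations, float))
        mixes = []
        for p in range(N_PEAKS):
            pts = np.column_stack([latencies[:, p], elevations[:, p]])
            pts = pts[np.all(np.isfinite(pts), axis=1)]
            if pts.shape[0] < 2:
                raise ValueError(f"too few annotated beats to fit the prior for peak {p + 1}")
            gm = GaussianMixture(
                n_components=min(n_components, pts.shape[0]),
                covariance_type="full",
                random_state=seed,
                reg_covar=1e-6,
            )
            gm.fit(pts)
            mixes.append(gm)
        return cls(mixtures=mixes)

    def log_likelihood(self, peak: int, latency_ms: float, elevation: float) -> float:
        return float(self.mixtures[peak].score_samples([[latency_ms, elevation]])[0])


def mocaip_designate(
    cands: CandidateSet, prior: MocaipPrior
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pick the ordered candidate triple with maximal prior log-likelihood.

    Returns (latencies (3,), elevations (3,), missing flags (3,)); all
    missing when the candidate set is empty or has fewer than three
    candidates.
    """
    m = len(cands)
    if m < N_PEAKS:
        return (np.full(N_PEAKS, np.nan), np.full(N_PEAKS, np.nan), np.ones(N_PEAKS, bool))
    # candidates are sorted by latency, so index combinations are ordered triples
    scores = np.array(
        [
            [prior.log_likelihood(p, cands.latencies_ms[i], cands.elevations[i]) for p in range(N_PEAKS)]
            for i in range(m)
        ]
    )
    best, best_triple = -np.inf, None
    for triple in itertools.combinations(range(m), N_PEAKS):
        s = scores[triple[0], 0] + scores[triple[1], 1] + scores[triple[2], 2]
        if s > best:
            best, best_triple = s, triple
    idx = np.array(best_triple)
    return (cands.latencies_ms[idx].copy(), cands.elevations[idx].copy(), np.zeros(N_PEAKS, bool))


def mocaip_representative_pulse(window: list[Pulse]) -> Pulse:
    """Representative beat of a window via hierarchical clustering.

    Correlation distance + average linkage; the representative is the mean
    pulse of the largest cluster (cut at correlation distance 0.3), which
    suppresses outlier beats.
    """
    window = [p for p in window if p is not None]
    if not window:
        raise ValueError("empty window")
    if len(window) == 1:
        return window[0]
    M = np.vstack([p.samples for p in window])
    sd = M.std(axis=1)
    if np.any(sd < 1e-12):  # constant beats break correlation distance
        return Pulse(M.mean(axis=0), fs=window[0].fs)
    d = pdist(M, metric="correlation")
    if np.allclose(d, 0):
        return Pulse(M.mean(axis=0), fs=window[0].fs)
    Z = sch.linkage(d, method="average")
    labels = sch.fcluster(Z, t=0.3, criterion="distance")
    counts = np.bincount(labels)
    biggest = int(np.argmax(counts))
    return Pulse(M[labels == biggest].mean(axis=0), fs=window[0].fs)


def mocaip_track(
    seq: PulseSequence,
    prior: MocaipPrior,
    window: int = 60,
    smooth_window: int = 11,
) -> TrackOutput:
    """Windowed MOCAIP over a beat sequence.

    Each window of ``window`` consecutive beats is reduced to a
    representative pulse whose designated peaks are assigned to every beat
    of the window — including masked beats, for which the source flag reads
    'inferred-from-prior'.  A window with no available beat reuses the
    previous designation.
    """
    n = len(seq)
    lat = np.full((n, N_PEAKS), np.nan)
    elev = np.full((n, N_PEAKS), np.nan)
    source = np.array(["observed"] * n, dtype=object)
    prev = None
    for start in range(0, n, window):
        stop = min(start + window, n)
        pulses = [seq.pulses[i] for i in range(start, stop) if seq.mask[i]]
        if pulses:
            rep = mocaip_representative_pulse(pulses)
            cands = mocaip_candidates(rep, smooth_window=smooth_window)
            trip = mocaip_designate(cands, prior)
            prev = trip
        if prev is None:
            raise ValueError("sequence starts with an all-masked window")
        tl, te, tm = prev
        for i in range(start, stop):
            lat[i], elev[i] = tl, te
            source[i] = "observed" if seq.mask[i] else "inferred-from-prior"
    return TrackOutput(latencies_ms=lat, elevations=elev, source=np.asarray(source))
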