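"""Preprocessing of segmented beats into fixed-length normalized vectors.

Heart rate varies, so beat lengths vary; every beat is (1) linearly
resampled to 400 samples, (2) circularly shifted so that its minimum becomes
the first element (a heart-rate-independent alignment point), and (3) scaled
so its area under the curve (sample sum) is 1, removing the unreliable
absolute pressure magnitude.  Peak annotations are mapped through the same
transforms (and back), so detector targets remain in original beat time (ms)
while features live in the normalized, aligned coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import PeakAnnotation, Pulse

__all__ = [
    "PreprocessedPulse",
    "resample_pulse",
    "align_pulse",
    "normalize_auc",
    "preprocess_pulse",
    "map_annotation",
    "unmap_annotation",
]

TARGET_LEN = 400


@dataclass
class PreprocessedPulse:
    """A resampled, aligned, AUC-normalized beat plus its transform record."""

    vector: np.ndarray         # length target_len, sums to 1, min at index 0
    shift: int                 # circular alignment offset, in resampled samples
    source_fs: float
    source_duration_ms: float
    auc_scale: float           # normalization divisor (sample sum pre-scaling)

    @property
    def target_len(self) -> int:
        return int(self.vector.size)


def resample_pulse(p: Pulse, target_len: int = TARGET_LEN) -> np.ndarray:
    """Linear interpolation of a beat onto target_len uniform points.

    The new grid spans the beat's sample support, endpoints preserved.
    """
    x = np.asarray(p.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("pulse contains non-finite samples")
    n0 = x.size
    grid = np.linspace(0.0, n0 - 1.0, target_len)
    return np.interp(grid, np.arange(n0), x)


def align_pulse(v: np.ndarray) -> tuple[np.ndarray, int]:
    """Circularly shift so the (first) minimum becomes element 0."""
    v = np.asarray(v, dtype=float)
    shift = int(np.argmin(v))
    return np.roll(v, -shift), shift


def normalize_auc(v: np.ndarray) -> np.ndarray:
    """Scale so the sample sum (AUC) is 1."""
    v = np.asarray(v, dtype=float)
    s = v.sum()
    if abs(s) < 1e-12:
        raise ValueError("degenerate beat: zero area under the curve")
    return v / s


def preprocess_pulse(p: Pulse, target_len: int = TARGET_LEN) -> PreprocessedPulse:
    """Full chain: resample -> align -> AUC-normalize."""
    r = resample_pulse(p, target_len)
    a, shift = align_pulse(r)
    s = a.sum()
    if abs(s) < 1e-12:
        raise ValueError("degenerate beat: zero area under the curve")
    return PreprocessedPulse(
        vector=a / s,
        shift=shift,
        source_fs=p.fs,
        source_duration_ms=p.duration_ms,
        auc_scale=s,
    )


def _lat_to_resampled_index(lat_ms: np.ndarray, pp: PreprocessedPulse) -> np.ndarray:
    n0 = pp.source_duration_ms * pp.source_fs / 1000.0  # original sample count
    orig_idx = np.asarray(lat_ms, dtype=float) * pp.source_fs / 1000.0
    return orig_idx * (pp.target_len - 1) / (n0 - 1)


def map_annotation(a: PeakAnnotation, pp: PreprocessedPulse) -> tuple[np.ndarray, np.ndarray]:
    """Map (latency ms, elevation) into preprocessed coordinates.

    Returns (index in the aligned 400-vector as float, normalized elevation).
    Latencies wrap modulo target_len under the circular shift.
    """
    lat = np.asarray(a.latencies_ms, dtype=float)
    if np.any((lat[~a.missing] < 0) | (lat[~a.missing] > pp.source_duration_ms)):
        raise ValueError("latency outside the beat")
    idx = np.mod(_lat_to_resampled_index(lat, pp) - pp.shift, pp.target_len)
    elev = np.asarray(a.elevations, dtype=float) / pp.auc_scale
    return idx, elev


def unmap_annotation(idx: np.ndarray, elev_norm: np.ndarray, pp: PreprocessedPulse) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`map_annotation`: preprocessed coords -> (ms, elevation)."""
    n0 = pp.source_duration_ms * pp.source_fs / 1000.0
    orig_idx = np.mod(np.asarray(idx, dtype=float) + pp.shift, pp.target_len) * (n0 - 1) / (pp.target_len - 1)
    lat_ms = orig_idx * 1000.0 / pp.source_fs
    return lat_ms, np.asarray(elev_norm, dtype=float) * pp.auc_scale
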