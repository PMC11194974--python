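"""Core containers for segmented intracranial-pressure (ICP) beats.

A single cardiac cycle of the ICP signal is *triphasic*: it carries three
sub-peaks (P1 percussion, P2 tidal, P3 dicrotic).  Each peak is described by
its latency ``l`` (time from beat onset, ms) and elevation ``e`` (pressure
height).  These containers hold segmented beats, their peak annotations, and
ordered sequences of beats with an availability mask for missing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["Pulse", "PeakAnnotation", "PulseSequence", "N_PEAKS"]

N_PEAKS = 3


@dataclass
class Pulse:
    """One segmented beat: pressure samples at a fixed sample rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a pulse needs a 1-D array of at least 2 samples")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        """Beat duration in ms (samples span [0, duration))."""
        return self.n_samples / self.fs * 1000.0

    def value_at(self, latency_ms: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated pressure at the given latency (ms)."""
        t = np.arange(self.n_samples) / self.fs * 1000.0
        return np.interp(latency_ms, t, self.samples)


@dataclass
class PeakAnnotation:
    """Latency (ms from beat onset) and elevation for p1, p2, p3.

    ``missing[i]`` marks a peak that is absent from this beat (no latency /
    elevation defined).  ``fallback[i]`` flags groundtruth produced from a
    mixture-component centre because bump overlap suppressed the local
    maximum (simulator provenance only).
    """

    latencies_ms: np.ndarray
    elevations: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]
    fallback: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.latencies_ms = np.ravel(np.asarray(self.latencies_ms, dtype=float))
        k = self.latencies_ms.size
        self.elevations = np.asarray(self.elevations, dtype=float).reshape(k)
        if self.missing is None:
            self.missing = np.zeros(k, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool).reshape(k)
        if self.fallback is None:
            self.fallback = np.zeros(k, dtype=bool)
        self.fallback = np.asarray(self.fallback, dtype=bool).reshape(k)
        present = self.latencies_ms[~self.missing]
        if present.size > 1 and not np.all(np.diff(present) > 0):
            raise ValueError("peak latencies must be strictly increasing")


@dataclass
class PulseSequence:
    """Ordered beats with annotations, a patient id, and availability mask.

    Masked (unavailable) beats carry ``None`` in ``pulses`` and
    ``annotations``; the boolean ``mask`` is True where the beat is observed.
    """

    pulses: list
    annotations: list
    patient_id: str = "sim"
    mask: Optional[np.ndarray] = None
    fs: float = 400.0

    def __post_init__(self) -> None:
        n = len(self.pulses)
        if len(self.annotations) != n:
            raise ValueError("pulses and annotations length mismatch")
        if self.mask is None:
            self.mask = np.array([p is not None for p in self.pulses], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool).reshape(n)
        for i, avail in enumerate(self.mask):
            if avail and self.pulses[i] is None:
                raise ValueError(f"beat {i} marked available but has no waveform")
            if not avail and (self.pulses[i] is not None or self.annotations[i] is not None):
                raise ValueError(f"beat {i} masked but carries data")

    def __len__(self) -> int:
        return len(self.pulses)

    @property
    def n_available(self) -> int:
        return int(self.mask.sum())

    def latency_matrix(self) -> np.ndarray:
        """(n_beats, 3) latencies in ms; NaN where masked or peak missing."""
        out = np.full((len(self), N_PEAKS), np.nan)
        for i, a in enumerate(self.annotations):
            if a is not None:
                out[i] = np.where(a.missing, np.nan, a.latencies_ms)
        return out

    def elevation_matrix(self) -> np.ndarray:
        """(n_beats, 3) elevations; NaN where masked or peak missing."""
        out = np.full((len(self), N_PEAKS), np.nan)
        for i, a in enumerate(self.annotations):
            if a is not None:
                out[i] = np.where(a.missing, np.nan, a.elevations)
        return out

    def waveform_matrix(self) -> np.ndarray:
        """(n_beats, n_samples) samples; NaN rows for masked beats."""
        ns = next(p.n_samples for p in self.pulses if p is not None)
        out = np.full((len(self), ns), np.nan)
        for i, p in enumerate(self.pulses):
            if p is not None:
                out[i] = p.samples
        return out

    def available_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def subset(self, indices: Sequence[int]) -> "PulseSequence":
        idx = list(indices)
        return PulseSequence(
            pulses=[self.pulses[i] for i in idx],
            annotations=[self.annotations[i] for i in idx],
            patient_id=self.patient_id,
            mask=self.mask[idx].copy(),
            fs=self.fs,
        )
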