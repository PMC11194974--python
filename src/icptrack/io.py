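"""Sequence files (HDF5), annotation tables (CSV), run configuration (YAML).

HDF5 schema per sequence file:

    pulses       (n_beats, n_samples) float64; NaN rows for masked beats
    fs           scalar
    mask         (n_beats,) bool
    annotations  (n_beats, 9): lat1..3 (ms), elev1..3, missing1..3 flags;
                 NaN rows for masked beats
    attrs        patient_id, duration_ms, provenance (JSON string)

Annotation CSVs use ms latency units and empty cells as the missing-value
marker.  Write -> read round trips are lossless (floats bit-identical).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import N_PEAKS, PeakAnnotation, Pulse, PulseSequence

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_annotations",
    "read_annotations",
    "load_config",
    "RunConfig",
]

_REQUIRED_DATASETS = ("pulses", "fs", "mask", "annotations")

_KNOWN_SECTIONS = {"simulator", "preprocess", "detector", "tracker", "evaluation", "seed", "out_dir"}


def write_sequence(path, seq: PulseSequence, provenance: Optional[dict] = None) -> None:
    path = Path(path)
    wav = seq.waveform_matrix()
    ann = np.full((len(seq), 3 * N_PEAKS), np.nan)
    for i, a in enumerate(seq.annotations):
        if a is not None:
            ann[i, :3] = a.latencies_ms
            ann[i, 3:6] = a.elevations
            ann[i, 6:9] = a.missing.astype(float)
    with h5py.File(path, "w") as f:
        # track_times=False keeps identical runs byte-identical
        f.create_dataset("pulses", data=wav, track_times=False)
        f.create_dataset("fs", data=float(seq.fs), track_times=False)
        f.create_dataset("mask", data=seq.mask.astype(bool), track_times=False)
        f.create_dataset("annotations", data=ann, track_times=False)
        f.attrs["patient_id"] = seq.patient_id
        f.attrs["provenance"] = json.dumps(provenance or {})


def read_sequence(path) -> PulseSequence:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise ValueError(f"sequence file {path} lacks dataset {name!r}")
        wav = f["pulses"][...]
        fs = float(f["fs"][()])
        mask = f["mask"][...].astype(bool)
        ann = f["annotations"][...]
        patient_id = str(f.attrs.get("patient_id", "unknown"))
    pulses, anns = [], []
    for i in range(wav.shape[0]):
        if mask[i]:
            pulses.append(Pulse(wav[i], fs=fs))
            anns.append(
                PeakAnnotation(
                    latencies_ms=ann[i, :3],
                    elevations=ann[i, 3:6],
                    missing=ann[i, 6:9] > 0.5,
                )
            )
        else:
            pulses.append(None)
            anns.append(None)
    return PulseSequence(pulses=pulses, annotations=anns, patient_id=patient_id, mask=mask, fs=fs)


_ANN_COLUMNS = [
    "beat",
    "p1_lat_ms", "p1_elev", "p1_missing",
    "p2_lat_ms", "p2_elev", "p2_missing",
    "p3_lat_ms", "p3_elev", "p3_missing",
    "available",
]


def write_annotations(path, seq: PulseSequence) -> None:
    rows = []
    for i, a in enumerate(seq.annotations):
        row = {"beat": i, "available": bool(seq.mask[i])}
        for p in range(N_PEAKS):
            key = f"p{p + 1}"
            if a is None or a.missing[p]:
                row[f"{key}_lat_ms"] = np.nan
                row[f"{key}_elev"] = np.nan
                row[f"{key}_missing"] = True
            else:
                row[f"{key}_lat_ms"] = a.latencies_ms[p]
                row[f"{key}_elev"] = a.elevations[p]
                row[f"{key}_missing"] = False
        rows.append(row)
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing_cols = set(_ANN_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"annotation file lacks columns {sorted(missing_cols)}")
    return df


class RunConfig(dict):
    """Validated run configuration (plain nested dict, unknown keys rejected)."""

    def __init__(self, data: Optional[dict] = None):
        data = data or {}
        unknown = set(data) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        super().__init__(data)

    def section(self, name: str) -> dict:
        return dict(self.get(name, {}) or {})


def load_config(path) -> RunConfig:
    with open(path) as f:
        return RunConfig(yaml.safe_load(f) or {})
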