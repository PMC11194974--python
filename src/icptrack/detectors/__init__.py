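"""Single-pulse peak detectors: regression from a preprocessed beat to the
three peak latencies."""

from .base import DetectorOutput, PeakDetector, predict_peaks
from .lstm import LSTMDetector
from .nn import NeuralNetworkDetector
from .spectral import AffinityGraph, SpectralRegression, build_affinity, graph_smoothness
from .svr import SupportVectorDetector, SVRModel
from .trees import GaussianSplitForest

__all__ = [
    "PeakDetector",
    "DetectorOutput",
    "predict_peaks",
    "AffinityGraph",
    "build_affinity",
    "graph_smoothness",
    "SpectralRegression",
    "SupportVectorDetector",
    "SVRModel",
    "NeuralNetworkDetector",
    "GaussianSplitForest",
    "LSTMDetector",
]

DETECTOR_NAMES = ("sr", "ksr", "svr", "nn", "trees", "lstm")


def make_detector(name: str, seed: int = 0, **params) -> PeakDetector:
    """Factory used by the evaluation harness and the CLI."""
    name = name.lower()
    if name == "sr":
        return SpectralRegression(kernelized=False, **params)
    if name == "ksr":
        return SpectralRegression(kernelized=True, **params)
    if name == "svr":
        return SupportVectorDetector(**params)
    if name == "nn":
        return NeuralNetworkDetector(seed=seed, **params)
    if name == "trees":
        return GaussianSplitForest(seed=seed, **params)
    if name == "lstm":
        return LSTMDetector(seed=seed, **params)
    raise ValueError(f"unknown detector {name!r}")
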