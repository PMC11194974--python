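"""Seed fan-out.

One root seed is expanded into independent named substreams (dynamics, noise,
missing, model initialisation, ...) so that individual experiment components
are reproducible in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic 31-bit seed for the named substream of ``root_seed``."""
    h = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of ``root_seed``."""
    return np.random.default_rng(substream_seed(root_seed, name))
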