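"""Deterministic seed splitting.

All randomness in the package flows from one integer seed.  Sub-streams
(root architecture, scatter artifacts, sensor noise, train/test splits, ...)
are derived by hashing string labels into a ``numpy.random.SeedSequence``
spawn key, so each stage is independently reproducible and adding a new
stage never perturbs existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def substream(seed: int, *labels: str | int) -> np.random.Generator:
    """Return a Generator for the sub-stream named by ``labels``."""
    key = tuple(_key(l) if isinstance(l, str) else int(l) for l in labels)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed), spawn_key=key)))


def subseed(seed: int, *labels: str | int) -> int:
    """A plain integer seed (< 2**31) derived from a labelled sub-stream."""
    return int(substream(seed, *labels).integers(0, 2**31 - 1))
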