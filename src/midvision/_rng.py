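"""Deterministic random-stream management.

A single master seed is fanned out into named substreams, one per pipeline
stage, so that e.g. changing the decoding seed never perturbs the simulated
recordings.  Substreams are derived by hashing the stage name into a
``numpy.random.SeedSequence`` spawn key, which is stable across platforms and
numpy versions.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _name_key(name: str) -> int:
    # crc32 is stable and fits comfortably in a SeedSequence entropy word
    return zlib.crc32(name.encode("utf-8"))


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return an independent ``Generator`` for stage *name* under *master_seed*."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), _name_key(name)]))


def subseed(master_seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) derived from the named substream.

    Useful for libraries that take an ``int`` seed (e.g. scikit-learn).
    """
    return int(substream(master_seed, name).integers(0, 2**31 - 1))
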