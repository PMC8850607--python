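"""Named random-number streams.

A single integer seed drives the whole package; each stochastic operation
draws from its own named substream so that, e.g., simulating states and
generating observation noise with the same top-level seed never share draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["named_rng", "named_seedseq"]


def named_seedseq(seed: int, name: str) -> np.random.SeedSequence:
    """Seed sequence for stream ``name`` derived from the integer ``seed``."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def named_rng(seed: int, name: str) -> np.random.Generator:
    """Generator for the substream identified by (seed, name)."""
    return np.random.default_rng(named_seedseq(seed, name))
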