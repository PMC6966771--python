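"""Seed fan-out helpers.

Every stochastic operation in the package derives its generator from a
single root seed plus a tuple of context keys (run index, target label,
surrogate phase, ...).  This makes whole experiments reproducible from one
integer while keeping independent substreams decorrelated.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_sequence", "substream"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def seed_sequence(root_seed: int, *keys) -> np.random.SeedSequence:
    """Deterministic child seed sequence for (root, *keys)."""
    entropy = [int(root_seed) & 0xFFFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def substream(root_seed: int, *keys) -> np.random.Generator:
    """A fresh Generator on the substream identified by (root, *keys)."""
    return np.random.default_rng(seed_sequence(root_seed, *keys))
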