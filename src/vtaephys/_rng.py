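"""Seeding helpers: one root seed, stable per-entity child streams.

Child generators are derived from the root seed plus a stable hash of
string keys (e.g. neuron id, drug name), so results for one neuron do not
depend on processing order and are reproducible across runs and platforms.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_rng", "as_rng"]


def _stable_key(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    digest = hashlib.sha256(str(key).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def child_rng(root_seed: int, *keys) -> np.random.Generator:
    """Generator for entity ``keys`` under ``root_seed`` (order-independent)."""
    entropy = [int(root_seed) & 0x7FFFFFFF] + [_stable_key(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
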