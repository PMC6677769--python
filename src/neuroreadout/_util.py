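"""Seeding helpers shared across the package.

Every stochastic stage draws from a stream derived from a top-level seed plus
a stage label, so adding or reordering stages never perturbs earlier streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for", "as_rng"]


def derive_seed(seed: int, label: str) -> int:
    """Derive a sub-seed (< 2**31) from a top-level seed and a stage label."""
    return int(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]).generate_state(1)[0] % (2**31))


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Named random stream for one pipeline stage."""
    return np.random.default_rng(derive_seed(seed, label))


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
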