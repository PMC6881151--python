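"""Deterministic stream-splitting for every stochastic element.

All surrogates, null-distribution caches and tie-breaking noise derive
their generators from a single master seed plus a tuple of context keys
(strings or small integers), so that independent components never share a
stream and results are bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode()) & 0x7FFFFFFF


def seed_sequence(master_seed: int, *keys) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys])


def substream(master_seed: int, *keys) -> np.random.Generator:
    """A generator unique to (master_seed, *keys), independent across keys."""
    return np.random.default_rng(seed_sequence(master_seed, *keys))


def derive_seed(master_seed: int, *keys) -> int:
    """A 31-bit child seed for APIs that take plain integer seeds."""
    return int(seed_sequence(master_seed, *keys).generate_state(1)[0] & 0x7FFFFFFF)
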