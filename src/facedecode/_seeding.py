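"""Named random substreams derived from one master seed.

Every stochastic component draws from ``rng_for(master_seed, *keys)`` so a
single integer reproduces the whole pipeline while stages and participants
stay statistically independent of each other.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    return zlib.crc32(repr(key).encode()) & 0x7FFFFFFF


def seed_sequence(master_seed: int, *keys) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed,
                                  spawn_key=tuple(_key_to_int(k) for k in keys))


def rng_for(master_seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(seed_sequence(master_seed, *keys))


def int_seed(master_seed: int, *keys) -> int:
    """A plain integer seed (< 2^31) for APIs that take one."""
    return int(seed_sequence(master_seed, *keys).generate_state(1)[0] & 0x7FFFFFFF)
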