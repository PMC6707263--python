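"""Deterministic substream derivation from a single master seed.

Every stochastic component (graph generation, seed-node choice, each
simulation realization, Monte-Carlo oracles) draws from its own named
substream so that ensembles are reproducible and statistically independent
regardless of evaluation order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "generator", "uint31"]


def _key_ints(keys) -> tuple[int, ...]:
    out = []
    for key in keys:
        if isinstance(key, (int, np.integer)):
            out.append(int(key) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(key).encode()))
    return tuple(out)


def substream(master_seed: int, *keys) -> np.random.SeedSequence:
    """A SeedSequence uniquely determined by the master seed and key path."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=_key_ints(keys))


def generator(master_seed: int, *keys) -> np.random.Generator:
    """A PCG64 generator on the named substream."""
    return np.random.Generator(np.random.PCG64(substream(master_seed, *keys)))


def uint31(master_seed: int, *keys) -> int:
    """A 31-bit integer seed for components that take a plain int seed."""
    return int(substream(master_seed, *keys).generate_state(1)[0] & 0x7FFFFFFF)
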