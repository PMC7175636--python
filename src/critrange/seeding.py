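"""Deterministic seed derivation.

Every stochastic routine takes a single master seed.  Replicate ``r`` of an
experiment named ``name`` draws from a generator seeded by
``SeedSequence([master, crc32(name), r])``, so any single replicate can be
reproduced in isolation and results do not depend on batching.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["experiment_rng", "replicate_rngs", "child_seed"]


def _token(name: str) -> int:
    return zlib.crc32(name.encode("utf8")) & 0x7FFFFFFF


def child_seed(master: int, name: str, replicate: int | None = None) -> np.random.SeedSequence:
    """SeedSequence for one experiment (and optionally one replicate)."""
    entropy = [int(master) & 0x7FFFFFFF, _token(name)]
    if replicate is not None:
        entropy.append(int(replicate))
    return np.random.SeedSequence(entropy)


def experiment_rng(master: int, name: str) -> np.random.Generator:
    """One generator for a whole (vectorised) experiment."""
    return np.random.default_rng(child_seed(master, name))


def replicate_rngs(master: int, name: str, reps: int):
    """Yield ``reps`` independent generators, one per replicate."""
    for r in range(reps):
        yield np.random.default_rng(child_seed(master, name, r))
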