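"""Deterministic seed derivation.

Every stochastic stage of a run draws from a child stream derived from one
master seed, a stage name and an index, so a whole experiment is reproducible
from a single integer and independent stages never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def child_seed(master: int, stage: str, index: int = 0) -> int:
    """Derive a sub-seed < 2**31 from ``master`` for a named stage."""
    entropy = [int(master) % _MOD, zlib.crc32(stage.encode("utf-8")), int(index)]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % _MOD)


def rng_for(master: int | None, stage: str, index: int = 0) -> np.random.Generator:
    """Generator for a named stage; unseeded when ``master`` is None."""
    if master is None:
        return np.random.default_rng()
    return np.random.default_rng(child_seed(master, stage, index))
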