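"""Deterministic hierarchical seeding.

A single integer seed drives every simulation; each sub-simulation derives a
child generator from the master seed plus a string path (e.g.
``("growth", "A", "monoculture", 3)``), so adding or reordering one stage
never perturbs the random stream of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Generator for the sub-stream identified by ``keys`` under ``seed``."""
    tag = zlib.crc32("/".join(str(k) for k in keys).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def child_seed(seed: int, *keys: object) -> int:
    """A plain integer child seed (< 2**31) for APIs that take one."""
    tag = zlib.crc32("/".join(str(k) for k in keys).encode("utf-8"))
    return int((int(seed) & 0x7FFFFFFF) ^ (tag & 0x7FFFFFFF))
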