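"""Hierarchical seeding: one master seed, per-stage/per-subject children.

Every stochastic operation derives its generator from
``(master_seed, stage, subject)`` so any stage can be re-run in isolation
and still reproduce the full-pipeline draw exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def child_seed(master: int, *keys: int | str) -> np.random.SeedSequence:
    """Seed sequence for a named child stream of ``master``."""
    return np.random.SeedSequence([int(master) & 0xFFFFFFFF, *map(_key_to_int, keys)])


def child_rng(master: int, *keys: int | str) -> np.random.Generator:
    """Generator for a named child stream of ``master``."""
    return np.random.default_rng(child_seed(master, *keys))
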