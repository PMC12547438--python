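"""Deterministic seed derivation.

Every stochastic stage derives its seed from a master seed plus a string/int
tag path, so the whole pipeline is a pure function of (data, params, seed).
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def derive_seed(base: int, *tags: int | str) -> int:
    """Derive a child seed from ``base`` and a tag path.

    String tags are hashed with crc32 so the derivation is stable across
    platforms and Python processes (unlike ``hash``).
    """
    parts = [int(base) % _MOD]
    for t in tags:
        if isinstance(t, str):
            parts.append(zlib.crc32(t.encode("utf-8")))
        else:
            parts.append(int(t) % _MOD)
    ss = np.random.SeedSequence(parts)
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % _MOD


def rng_from(base: int, *tags: int | str) -> np.random.Generator:
    """A fresh ``numpy`` generator for the given tag path."""
    return np.random.default_rng(derive_seed(base, *tags))
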