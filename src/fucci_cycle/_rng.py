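"""Seed plumbing: every source of randomness flows from one top-level seed.

Named substreams are derived with ``numpy.random.SeedSequence`` spawn keys so
that adding a new consumer never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_part(name: object) -> int:
    if isinstance(name, (int, np.integer)):
        return int(name) % (2**31)
    return zlib.crc32(str(name).encode())


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    ``names`` may mix strings and integers; strings are hashed with CRC32 so
    the mapping is stable across processes and Python versions.
    """
    key = tuple(_key_part(n) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))
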