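"""Seeded random substreams.

All randomness in the package flows from one top-level integer seed.
Independent, reproducible substreams are derived per named purpose
(e.g. per sample) so that adding or reordering samples never perturbs
the draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def stable_hash(*keys: object) -> int:
    """Deterministic 32-bit hash of a tuple of keys (platform independent)."""
    blob = "\x1f".join(str(k) for k in keys).encode()
    return zlib.crc32(blob)


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a generator for the substream named by ``keys`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stable_hash(*keys)]))
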