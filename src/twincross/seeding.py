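"""Deterministic sub-seed derivation.

Every stochastic stage consumes a sub-seed derived from one global 64-bit
run seed.  The splitting scheme is: the global seed plus the CRC-32 of each
string tag are fed, in order, to :class:`numpy.random.SeedSequence`, whose
first generated word is the stage seed.  The scheme is stable across runs,
platforms and numpy versions.
"""

from __future__ import annotations

import zlib

import numpy as np


def subseed(seed: int, *tags: object) -> int:
    """Derive a stage sub-seed from a global seed and a tag path.

    Parameters
    ----------
    seed:
        Global run seed (any Python int).
    *tags:
        Hashable stage labels, e.g. ``("simulate", "GU", 3)``.  Tags are
        stringified, so ``3`` and ``"3"`` collide intentionally.
    """
    entropy = [int(seed) & 0xFFFFFFFFFFFFFFFF]
    entropy.extend(zlib.crc32(str(t).encode("utf-8")) for t in tags)
    return int(np.random.SeedSequence(entropy).generate_state(1)[0])


def rng_for(seed: int, *tags: object) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded via :func:`subseed`."""
    return np.random.default_rng(subseed(seed, *tags))
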