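"""Deterministic derivation of child seeds from one experiment seed.

Every run / fold / per-node model gets its own seed derived from the base
seed and a key path, so any piece of a seeded experiment can be re-run in
isolation with identical results.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(base: int, *keys: int | str) -> int:
    """A reproducible seed (< 2**31) for the given key path under ``base``."""
    ints = [int(base)]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k))
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
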