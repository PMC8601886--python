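"""Counter-based seed derivation.

Every stochastic operation draws from a generator derived from a root seed
plus a stable string tag (and optional integer counters), so reruns of any
single stage reproduce bit-for-bit without consuming shared RNG state.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(root_seed: int, *tags: str | int) -> np.random.Generator:
    """Generator keyed by (root_seed, tags); stable across processes."""
    keys = tuple(
        zlib.crc32(t.encode()) if isinstance(t, str) else int(t) & 0xFFFFFFFF
        for t in tags
    )
    return np.random.default_rng(np.random.SeedSequence(int(root_seed), spawn_key=keys))
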