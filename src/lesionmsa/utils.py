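"""Seed plumbing shared across modules.

All randomness flows from a single run seed through named substreams so
that every stage (grid search, bootstrap, permutation sampling, label
shuffles) is reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spawn_seeds", "spawn_rngs"]

# sklearn random_state must fit in a signed 32-bit int
_SEED_MAX = 2**31


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds (< 2^31) from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % _SEED_MAX for s in ss.generate_state(n, dtype=np.uint64)]


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent Generators from one seed."""
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]
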