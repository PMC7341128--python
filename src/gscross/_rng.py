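"""Seed handling.

Every public operation takes either an integer seed or an existing
:class:`numpy.random.Generator`.  Multi-stage procedures derive one child
seed per stage from the master seed with ``numpy.random.SeedSequence.spawn``
so that each stage is independently reproducible.
"""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seed sequences from one master seed."""
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n)
    return np.random.SeedSequence(seed).spawn(n)
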