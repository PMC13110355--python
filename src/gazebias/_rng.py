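"""Seed plumbing.

A single session seed is expanded into independent per-purpose substreams via
``numpy.random.SeedSequence.spawn`` so that trial-level reproducibility
survives reordering of the consuming code.
"""

from __future__ import annotations

import numpy as np


def rng_from(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    """Coerce a seed-like object to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one integer seed into ``n`` independent generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
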