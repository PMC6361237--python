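"""Seed plumbing: every stochastic operation accepts an int, None, a
SeedSequence or a Generator, and derives child streams via SeedSequence
spawning so whole runs reproduce bit-identically from one integer."""

from __future__ import annotations

import numpy as np


def as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        raise TypeError("pass an int/None/SeedSequence where child streams "
                        "must be spawned, not a Generator")
    return np.random.SeedSequence(seed)
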