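"""Deterministic RNG substream helpers.

Each public generator takes one integer seed; independent substreams are
derived with :class:`numpy.random.SeedSequence` so that adding a stage never
perturbs the draws of earlier stages.
"""

from __future__ import annotations

import numpy as np


def substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Return *n* independent generators derived from one integer seed."""
    children = np.random.SeedSequence(int(seed)).spawn(n)
    return [np.random.default_rng(c) for c in children]


def child_seed(seed: int, index: int) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    ss = np.random.SeedSequence(int(seed)).spawn(index + 1)[index]
    return int(ss.generate_state(1)[0] % (2**31 - 1))
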