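"""Seed handling: every stochastic routine accepts an int seed or a Generator."""

from __future__ import annotations

import hashlib

import numpy as np

SeedLike = "int | np.random.Generator | None"


def as_rng(seed) -> np.random.Generator:
    """Return a numpy Generator; ints/None are fed to default_rng, Generators pass through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _label_int(label: str) -> int:
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")


def substream(master_seed: int, label: str) -> np.random.Generator:
    """Named, replayable substream of a master seed (stable across sessions)."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), _label_int(label)]))
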