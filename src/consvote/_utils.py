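"""Shared helpers: deterministic seed derivation for multi-stage runs."""

from __future__ import annotations

import numpy as np

_MAX_SEED = 2**31 - 1


def derive_seed(root_seed: int, *tags: str | int) -> int:
    """Derive a stage seed from a run-level seed and a label path.

    Every stochastic stage of a run draws its own seed from the run seed and
    a stable string tag (e.g. ``derive_seed(42, "splits")``), so runs replay
    exactly while stages stay statistically independent.
    """
    ss = np.random.SeedSequence([int(root_seed) % _MAX_SEED] +
                                [_hash_tag(t) for t in tags])
    return int(ss.generate_state(1)[0] % _MAX_SEED)


def _hash_tag(tag: str | int) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) % _MAX_SEED
    h = 0
    for ch in str(tag):
        h = (h * 131 + ord(ch)) % _MAX_SEED
    return h


def rng_from(root_seed: int, *tags: str | int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root_seed, *tags))
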