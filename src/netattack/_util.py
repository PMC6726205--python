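"""Shared numeric helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf.

    Used for every fraction-to-count conversion (edge deletions/additions,
    sample quotas, removal counts) so all modules agree on the convention.
    """
    return int(math.floor(x + 0.5))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce None / int seed / Generator to a numpy Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
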