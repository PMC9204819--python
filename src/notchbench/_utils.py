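"""Shared helpers: seeded random streams and small numeric utilities."""

from __future__ import annotations

from typing import Iterable

import numpy as np

# log2 of the smallest positive intensity we distinguish from zero
_LOG2_FLOOR = -300.0


def named_streams(seed: int, names: Iterable[str]) -> dict[str, np.random.Generator]:
    """Derive one independent random generator per named stage from one seed.

    The streams are spawned from a single :class:`numpy.random.SeedSequence`
    in the (fixed) order of ``names``, so any stage is individually
    reproducible given the global seed.
    """
    names = list(names)
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def safe_log2(x: np.ndarray) -> np.ndarray:
    """log2 that maps non-positive values to a very small constant instead of -inf/nan."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, _LOG2_FLOOR)
    pos = x > 0
    out[pos] = np.log2(x[pos])
    return out
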