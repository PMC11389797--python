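"""Seed plumbing.

A single master seed fans out into named, independent substreams
(counts, distances, time series, bootstrap, classifier iterations, ...)
via :class:`numpy.random.SeedSequence`, so each stage can be regenerated
on its own without perturbing the others.
"""

from __future__ import annotations

import numpy as np

#: stable stream indices; append only, never reorder
_STREAMS = (
    "counts",
    "distances",
    "timeseries",
    "deg",
    "overlap",
    "classifier",
    "metrics",
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the generator for the named substream of ``seed``."""
    try:
        idx = _STREAMS.index(name)
    except ValueError as exc:  # pragma: no cover - programming error
        raise KeyError(f"unknown random substream {name!r}") from exc
    ss = np.random.SeedSequence(seed, spawn_key=(idx,))
    return np.random.default_rng(ss)


def iteration_seeds(seed: int, n: int, name: str = "classifier") -> np.ndarray:
    """Derive ``n`` independent 31-bit integer seeds for per-iteration use.

    Derivation is by counter, so the first k seeds are identical for any
    requested ``n >= k``: results at a reduced iteration count are a prefix
    of the full run.
    """
    idx = _STREAMS.index(name)
    ss = np.random.SeedSequence(seed, spawn_key=(idx,))
    return np.random.default_rng(ss).integers(0, 2**31 - 1, size=n)
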