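"""Seeded random-number substreams.

All stochastic stages derive their generators from a single master seed via
named substreams, so that any stage can be re-run in isolation and the whole
pipeline is reproducible from one integer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream is derived with ``np.random.SeedSequence(seed, spawn_key)``
    where the spawn key is built from the UTF-8 bytes of ``name``; distinct
    names yield independent streams, and the mapping is stable across runs.
    """
    key = tuple(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=seed, spawn_key=key)
    return np.random.default_rng(ss)
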