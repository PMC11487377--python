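"""Named random substreams.

One global seed fans out to independent, order-insensitive substreams so
that toggling one randomized stage (augmentation, fold split, weight init,
phantom geometry ...) never shifts the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage `name` derived from the global `seed`.

    The stream depends only on (seed, name): stable across runs and across
    call order.  Names are free-form labels such as "phantom", "folds",
    "augment/axial", "init/coronal".
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
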