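"""Random-stream plumbing.

A single root seed controls a whole run. Named child streams are spawned
from it so that, e.g., the TPE construction can be re-run without
perturbing the slope or error draws of a larger pipeline.
"""
from __future__ import annotations

import numpy as np

# Fixed spawn order: the index of a name in this tuple is its spawn key,
# so adding new names at the end never changes existing streams.
STREAM_NAMES = ("tpe", "slopes", "tau", "errors", "sampling", "breeding")


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def named_streams(seed: int, names=STREAM_NAMES) -> dict[str, np.random.Generator]:
    """Spawn one independent Generator per name from a single root seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(STREAM_NAMES))
    lookup = dict(zip(STREAM_NAMES, children))
    for name in names:
        if name not in lookup:
            raise KeyError(f"unknown stream name {name!r}; known: {STREAM_NAMES}")
    return {name: np.random.default_rng(lookup[name]) for name in names}
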