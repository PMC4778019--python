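"""Deterministic seed derivation for the generator sub-streams."""

from __future__ import annotations

import numpy as np

# fixed stream ids; never reorder, or previously generated studies change
STREAM_AFM = 1
STREAM_FIBRIL = 2
STREAM_CAPILLARY = 3
STREAM_OMICS = 4
STREAM_PANEL = 5


def child_rng(seed: int, *stream: int) -> np.random.Generator:
    """Independent generator for one artifact, keyed by (seed, stream...)."""
    return np.random.default_rng([int(seed) % 2**31, *map(int, stream)])
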