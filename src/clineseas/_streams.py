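"""Deterministic random-stream splitting.

One top-level integer seed drives the whole pipeline.  Each stage (or
sub-operation) obtains its own independent generator via a stable string
label, so any stage can be rerun in isolation and reproduce its draws
regardless of what other stages did.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return an independent ``Generator`` for (seed, label).

    The label is folded to a 31-bit integer with CRC-32 and combined
    with the seed in a ``SeedSequence``, so distinct labels yield
    statistically independent streams while staying reproducible.
    """
    tag = zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
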