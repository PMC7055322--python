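"""Named random substreams.

All randomness in the pipeline flows from one root seed.  Each consumer
asks for a substream by name; the stream is keyed by ``(seed, name)`` so
adding a new consumer never perturbs the draws of existing ones, and the
order in which streams are created is irrelevant.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Seed sequence for the substream ``name`` under root ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key])


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent :class:`numpy.random.Generator` keyed by (seed, name)."""
    return np.random.default_rng(substream_seed(seed, name))
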