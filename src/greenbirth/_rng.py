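"""Named random substreams derived from a single global seed.

Every stochastic stage draws from its own substream so a stage can be
re-run in isolation and still reproduce the numbers of a full run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the (seed, name) pair.

    The stream is a deterministic function of both arguments; different
    names under the same seed are statistically independent.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
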