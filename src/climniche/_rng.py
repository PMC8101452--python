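"""Named, independent random substreams derived from a single root seed.

Every stochastic stage (climate noise, GCM fields, virtual species, catalogue,
bootstraps, GCM draws) pulls its generator from ``substream(seed, name)`` so
that each stage is reproducible on its own and insensitive to the order in
which other stages consume randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of a root seed.

    The stream identity is ``(seed, crc32(name))``, folded into a
    ``SeedSequence`` so distinct names give statistically independent streams
    while the same ``(seed, name)`` pair is bit-reproducible across runs and
    platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
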