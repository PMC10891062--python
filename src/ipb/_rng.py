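"""Seed fan-out: one global seed derives named, independent RNG substreams.

Toggling the randomness consumed by one stage must not shift the draws seen
by the others, so every stage asks for its stream by name instead of sharing
a single generator.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_generator"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible RNG substream derived from ``seed``.

    The same ``(seed, name)`` pair always yields a generator producing the
    same draws; distinct names give statistically independent streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def as_generator(rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed / generator / ``None`` into a ``numpy.random.Generator``.

    Objects that already expose the generator interface (``uniform``) are
    passed through, so tests can inject scripted draw sequences.
    """
    if isinstance(rng, np.random.Generator) or hasattr(rng, "uniform"):
        return rng
    return np.random.default_rng(rng)
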