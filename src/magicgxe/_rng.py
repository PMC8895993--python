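"""Named, reproducible random substreams.

Every public operation takes a single integer seed and derives independent
generators for its internal sources of randomness by hashing the seed
together with a short string label.  The derivation is stable across runs
and platforms, so fixtures are bit-reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_words(keys: tuple) -> list[int]:
    words = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            words.append(int(k) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(k).encode("utf-8")))
    return words


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    Distinct key tuples give statistically independent streams; the same
    (seed, keys) pair always gives the same stream.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *_key_words(keys)])
    return np.random.default_rng(ss)
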