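"""Seeded, named random substreams.

All randomness in the package flows from a single root seed. Each logical
table (panel, roster, survey, ...) draws from its own named substream so
that adding draws to one generator never perturbs another. Substreams are
derived from ``numpy.random.SeedSequence`` with a CRC32 of the stream name
as spawn key, which is platform- and version-stable.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def derive_seed(seed: int, name: str) -> int:
    """A stable 31-bit integer seed for libraries that want a plain int."""
    key = zlib.crc32(name.encode("utf-8"))
    return int(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)).generate_state(1)[0] % (2**31))
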