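"""Named, reproducible random substreams.

All randomness in the package flows from one root seed. Each consumer asks
for a generator by name (and optional integer qualifiers, e.g. an epoch or
MC-pass index), so every stage of a run is independently reproducible and
two runs with the same root seed are bit-identical.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _name_key(name: str) -> int:
    # stable across processes and platforms, unlike hash()
    return zlib.crc32(name.encode("utf-8"))


def spawn_seed(root_seed: int, name: str, *indices: int) -> np.random.SeedSequence:
    """Derive a :class:`numpy.random.SeedSequence` for a named substream."""
    if root_seed < 0:
        raise ValueError("root seed must be non-negative")
    return np.random.SeedSequence([int(root_seed), _name_key(name), *map(int, indices)])


def substream(root_seed: int, name: str, *indices: int) -> np.random.Generator:
    """A fresh Generator for substream ``name`` of ``root_seed``.

    Calling twice with the same arguments yields identically-seeded
    generators; different names or indices give independent streams.
    """
    return np.random.default_rng(spawn_seed(root_seed, name, *indices))
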