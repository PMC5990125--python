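"""Named random substreams derived from one master seed.

Every stochastic component draws from ``substream(seed, "name", ...)`` so
that (a) the whole pipeline is reproducible from a single integer and
(b) changing one component's draws never perturbs another's.  Keys may be
strings (hashed stably with crc32) or integers.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys) -> np.random.Generator:
    """Generator for the substream addressed by (seed, *keys)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *map(_key_to_int, keys)])
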