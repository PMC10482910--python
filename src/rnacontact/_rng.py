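"""Named, reproducible random streams.

A single run seed fans out into independent per-purpose generators so that
e.g. the inpainting mask draw never consumes the jigsaw stream.  The name is
hashed stably (not with Python's randomised ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed from ``seed`` and ``name``."""
    return (int(seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31)


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for the stream ``name`` under run ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())]))
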