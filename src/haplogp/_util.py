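"""Shared helpers: named random streams and small numeric utilities."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["named_stream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed from (seed, stream name).

    All stage-level randomness flows from one master seed through named
    streams so that any stage can be regenerated independently.
    """
    h = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def named_stream(seed: int, name: str) -> np.random.Generator:
    """A Generator for the named stream rooted at ``seed``."""
    return np.random.default_rng(child_seed(seed, name))
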