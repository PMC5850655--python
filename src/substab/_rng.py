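"""Deterministic, order-independent random streams for bootstrap work.

Every replicate gets its own generator seeded from
``SeedSequence([user_seed, *stream_tokens, replicate_index])``, where the
stream tokens are a stable hash of what the replicate is for (e.g. a clade
and its outgroup).  Results are therefore invariant to the order in which
clades or replicates are evaluated, and independent streams never collide
regardless of evaluation order.
"""

from __future__ import annotations

import hashlib

import numpy as np

_SEED_MOD = 2**31


def stream_tokens(*parts: str) -> tuple[int, int]:
    """Two stable 32-bit tokens derived from the given string parts."""
    digest = hashlib.sha256("\x1f".join(parts).encode("utf-8")).digest()
    return (
        int.from_bytes(digest[:4], "big"),
        int.from_bytes(digest[4:8], "big"),
    )


def replicate_rng(seed: int, stream: tuple[int, ...], replicate: int) -> np.random.Generator:
    """Generator for one replicate of one stream."""
    entropy = [int(seed) % _SEED_MOD, *stream, int(replicate)]
    return np.random.default_rng(np.random.SeedSequence(entropy))
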