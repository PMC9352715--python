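"""Shared helpers: deterministic id ordering and seed derivation."""

from __future__ import annotations

import zlib

import numpy as np


def id_key(identifier: str):
    """Sort key for opaque ids: numeric ids sort numerically, others lexically.

    Numeric ids (ChEBI-style) come before non-numeric ones so that mixed
    catalogues still have a total, deterministic order.
    """
    s = str(identifier)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


def derive_rng(seed: int, *scope) -> np.random.Generator:
    """Derive an independent Generator from a global seed and a scope label.

    The scope (e.g. ("shuffle", user_id)) is hashed with crc32 so that
    per-user / per-stage streams are independent yet reproducible from the
    single global seed.
    """
    tags = [zlib.crc32(str(s).encode("utf-8")) for s in scope]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *tags]))
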