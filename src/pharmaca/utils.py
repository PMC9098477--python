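"""Seed derivation and JSON helpers shared across pipeline stages."""
from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master_seed: int, *tokens) -> int:
    """Deterministically derive a substream seed from a master seed and tokens.

    Tokens (strings or ints) name the consumer, e.g. ``("m2", "response")``,
    so every (mouse, stage, repeat) combination gets an independent,
    reproducible stream and partial re-runs reproduce exactly.  The result
    is kept below 2**31.
    """
    h = zlib.crc32(str(int(master_seed)).encode())
    for tok in tokens:
        h = zlib.crc32(str(tok).encode(), h)
    return h & 0x7FFFFFFF


def derive_rng(master_seed: int, *tokens) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *tokens))


def jsonify(obj):
    """Convert numpy scalars/arrays (and NaN) for deterministic JSON output."""
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [jsonify(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    return obj
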