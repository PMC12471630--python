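"""Shared helpers: deterministic seed derivation and small validators."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "as_rng", "check_square_symmetric"]


def derive_seed(master_seed: int, *tags: str | int) -> int:
    """Derive a stage-specific seed from a master seed by stable hashing.

    Keeps independent pipeline stages decoupled: consuming extra draws in one
    stage never shifts the random stream of another. The result is a 31-bit
    non-negative integer, stable across platforms and Python processes.
    """
    key = ":".join([str(int(master_seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, Generator or None) to a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def check_square_symmetric(a: np.ndarray, name: str = "matrix", atol: float = 1e-8) -> None:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=atol, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
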