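"""Small shared helpers: seed derivation and input checks."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "check_square_binary"]


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from one global seed.

    A fixed CRC32-based derivation so that one user-facing seed fans out into
    independent, reproducible streams per pipeline stage. Always < 2**31.
    """
    return zlib.crc32(f"{int(seed)}:{stage}".encode()) & 0x7FFFFFFF


def check_square_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mask.shape}")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask entries must be 0 or 1")
    return mask.astype(np.int8)
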