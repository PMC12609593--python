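"""Small shared helpers."""

from __future__ import annotations

import zlib

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def round_half_up(x) -> int | np.ndarray:
    """Round to the nearest integer with ties rounded up (0.5 -> 1).

    numpy/python use banker's rounding; conventionally reported copy
    numbers use the half-up rule.  Values here are nonnegative.
    """
    if np.ndim(x) == 0:
        return int(np.floor(float(x) + 0.5))
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def child_seed(seed: int, *salts) -> int:
    """Derive a deterministic sub-seed (< 2**31) from a master seed.

    Salts are hashed with crc32 so the derivation is stable across
    processes (unlike built-in ``hash`` on strings).
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(repr(s).encode()) & 0x7FFFFFFF for s in salts]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> uint8 byte array (upper-cased)."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
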