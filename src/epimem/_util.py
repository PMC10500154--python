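"""Shared helpers: seeding, small interval arithmetic, reverse complement."""

from __future__ import annotations

import hashlib

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.upper().encode().translate(_COMPLEMENT)[::-1].decode()


def stable_stream(master_seed: int, *tokens) -> np.random.Generator:
    """Derive an independent RNG stream from a master seed and string/int tokens.

    Uses SHA-256 of the token tuple so streams are stable across runs and
    platforms (Python's hash() is salted and unusable here).
    """
    h = hashlib.sha256(repr(tuple(tokens)).encode()).digest()
    key = int.from_bytes(h[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key]))


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union of half-open [start, end) intervals; returns a sorted (k, 2) array."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out)


def covered_bp(intervals: np.ndarray, start: int, end: int) -> int:
    """Base pairs of the union of intervals intersected with [start, end)."""
    total = 0
    for s, e in merge_intervals(intervals):
        total += max(0, min(e, end) - max(s, start))
    return total
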