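"""Low-level nucleotide sequence utilities shared across modules.

Sequences cross module boundaries as plain Python strings over the ACGT
alphabet; internally most algorithms work on numpy ``uint8`` arrays with the
encoding A=0, C=1, G=2, T=3. All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = chr(np.frombuffer(seq.encode(), dtype=np.uint8)[arr > 3][0])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 array back to an ACGT string."""
    return _DECODE[arr].tobytes().decode()


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def gc_content(seq: str) -> float:
    """Fraction of G+C bases; 0.0 for the empty sequence."""
    if not seq:
        return 0.0
    arr = encode(seq)
    return float(np.mean((arr == 1) | (arr == 2)))


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """I.i.d. random sequence of length ``n`` at expected GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=n, p=p).astype(np.uint8))


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all overlapping k-mers (base-4 big-endian), int64.

    Returns an empty array when the sequence is shorter than ``k``.
    ``k`` must be at most 31 so codes fit an int64.
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr.astype(np.int64), k)
    return windows @ powers


def hamming_windows(text: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Mismatch count of ``pattern`` against every window of ``text``.

    Vectorised sliding comparison; returns an array of length
    ``len(text) - len(pattern) + 1`` (empty if the text is shorter).
    """
    m = pattern.size
    if text.size < m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(text, m)
    return (windows != pattern).sum(axis=1)
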