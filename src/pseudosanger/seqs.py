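"""Nucleotide encoding helpers shared across the package.

Sequences are held as numpy ``uint8`` code arrays: A=0, C=1, G=2, T=3, N=4.
Code 4 (N) never matches any seed key and always counts as a mismatch in
alignment, so ambiguous bases are inert throughout the pipeline.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement table; N stays N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a string."""
    return _DECODE[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (last axis)."""
    return _COMP[codes][..., ::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def kmer_codes(rows: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer integers for every position of every row.

    ``rows`` is an (n, L) uint8 matrix; the result is (n, L-k+1) int64 where
    windows containing an N are set to -1. k must satisfy 2*k <= 62.
    """
    if rows.ndim == 1:
        rows = rows[None, :]
    n, L = rows.shape
    if L < k:
        return np.empty((n, 0), dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(rows, k, axis=1)
    weights = (np.int64(1) << (2 * np.arange(k, dtype=np.int64)))
    codes = (win.astype(np.int64) * weights).sum(axis=2)
    bad = (win == 4).any(axis=2)
    codes[bad] = -1
    return codes
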