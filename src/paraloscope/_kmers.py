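"""Vectorized k-mer encoding shared by discovery, copy-number and expression code.

K-mers over {A,C,G,T} are packed into uint64 codes (2 bits per base), so k <= 31.
Positions whose window contains a non-ACGT character get code INVALID.
"""
from __future__ import annotations

import numpy as np

INVALID = np.uint64(0xFFFFFFFFFFFFFFFF)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Per-base 2-bit codes (255 for non-ACGT)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _BASE_CODE[np.frombuffer(seq, dtype=np.uint8)]


def kmer_codes(seq: str | bytes, k: int) -> np.ndarray:
    """uint64 code of the k-mer starting at every position (INVALID where ambiguous)."""
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    base = seq_to_codes(seq)
    n = len(base) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = base > 3
    vals = base.astype(np.uint64)
    code = np.zeros(n, dtype=np.uint64)
    anybad = np.zeros(n, dtype=bool)
    for j in range(k):
        code = (code << np.uint64(2)) | vals[j : j + n]
        anybad |= bad[j : j + n]
    code[anybad] = INVALID
    return code


def revcomp_code(code: int, k: int) -> int:
    """Reverse-complement of a packed k-mer code."""
    rc = 0
    c = int(code)
    for _ in range(k):
        rc = (rc << 2) | (3 - (c & 3))
        c >>= 2
    return rc


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Elementwise min(code, revcomp(code)); INVALID preserved."""
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << np.uint64(2)) | (np.uint64(3) - (tmp & np.uint64(3)))
        tmp >>= np.uint64(2)
    out = np.minimum(codes, rc)
    out[codes == INVALID] = INVALID
    return out


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtN", "TGCAtgcaN"))[::-1]
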