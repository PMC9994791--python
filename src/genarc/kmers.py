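"""Vectorized k-mer coding.

A k-mer over A/C/G/T is represented as a ``uint64`` built from 2-bit codes
in alphabet order, so numeric comparison of equal-length k-mers coincides
with lexicographic comparison of their strings.  Windows containing any
non-ACGT symbol are flagged invalid and never become candidates or
splitters.
"""

from __future__ import annotations

import numpy as np

from .sequence import CODE2, CODE4, reverse_complement

_U2 = np.uint64(2)
_U4 = np.uint64(4)


def window_values(codes: np.ndarray, k: int, bits: int) -> np.ndarray:
    """Big-endian radix-2^bits values of all length-``k`` windows."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    shift = np.uint64(bits)
    vals = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        vals = (vals << shift) | codes[j : j + n].astype(np.uint64)
    return vals


def valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of windows free of invalid (255) codes."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    bad = (codes == 255).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(bad)])
    return (cum[k:] - cum[:-k]) == 0


def kmer_scan(seq: bytes, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand values and validity mask for all k-windows of ``seq``."""
    codes = CODE2[np.frombuffer(seq, dtype=np.uint8)]
    return window_values(codes, k, 2), valid_windows(codes, k)


def canonical_scan(seq: bytes, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (min of strand and reverse complement) k-mer values.

    Returns ``(values, valid)`` indexed by window start on the forward
    strand.  Invalid windows carry unspecified values.
    """
    fwd, valid = kmer_scan(seq, k)
    if len(fwd) == 0:
        return fwd, valid
    rc_seq = reverse_complement(_acgt_only(seq))
    rc_vals, _ = kmer_scan(rc_seq, k)
    # window i of seq corresponds to window n-k-i of the reverse complement
    rc_for_fwd = rc_vals[::-1]
    return np.minimum(fwd, rc_for_fwd), valid


def _acgt_only(seq: bytes) -> bytes:
    """Replace non-ACGT symbols with 'A' so reverse_complement is defined.

    Affected windows are invalid anyway, so the substituted values are
    never consulted.
    """
    arr = np.frombuffer(seq, dtype=np.uint8).copy()
    arr[CODE2[arr] == 255] = ord("A")
    return arr.tobytes()


def mmer_values(seq: bytes, m: int) -> np.ndarray:
    """4-bit-code window values over the full IUPAC alphabet (match finder).

    Requires ``m <= 16`` so the value fits in 64 bits.
    """
    if m > 16:
        raise ValueError("m must be <= 16 for 4-bit hashing")
    codes = CODE4[np.frombuffer(seq, dtype=np.uint8)]
    return window_values(codes, m, 4)


def value_to_kmer(value: int, k: int) -> bytes:
    """Decode a 2-bit packed k-mer value back to its ACGT string."""
    out = bytearray(k)
    alpha = b"ACGT"
    v = int(value)
    for i in range(k - 1, -1, -1):
        out[i] = alpha[v & 3]
        v >>= 2
    return bytes(out)


def canonical_value(kmer_value: int, k: int) -> int:
    """Canonical form of a single 2-bit packed k-mer value."""
    v = int(kmer_value)
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (v & 3))
        v >>= 2
    return min(int(kmer_value), rc)
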