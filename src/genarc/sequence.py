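"""Nucleotide alphabet handling: IUPAC validation, reverse complement,
canonical k-mers and radix packing of symbols into bytes.

Sequences are plain ``bytes`` of upper-case ASCII over the 16-letter IUPAC
nucleotide alphabet (A, C, G, T, U, R, Y, S, W, K, M, B, D, H, V, N).
Ingestion upper-cases and validates; everything downstream assumes valid
input.  Only A/C/G/T participate in k-mer canonicalization; windows that
contain any other symbol are skipped by the k-mer machinery.
"""

from __future__ import annotations

import numpy as np

IUPAC = b"ACGTURYSWKMBDHVN"

#: complement pairs.  U is kept self-complementary: mapping U to A (its
#: biochemical complement) would make the table 2-to-1 (T and U both -> A),
#: and an invertible, involutory complement is required for lossless
#: storage of reverse-complemented segments.
_COMPLEMENT_PAIRS = {
    ord("A"): ord("T"),
    ord("T"): ord("A"),
    ord("C"): ord("G"),
    ord("G"): ord("C"),
    ord("U"): ord("U"),
    ord("R"): ord("Y"),
    ord("Y"): ord("R"),
    ord("K"): ord("M"),
    ord("M"): ord("K"),
    ord("B"): ord("V"),
    ord("V"): ord("B"),
    ord("D"): ord("H"),
    ord("H"): ord("D"),
    ord("S"): ord("S"),
    ord("W"): ord("W"),
    ord("N"): ord("N"),
}

_COMPLEMENT_TABLE = bytes(
    _COMPLEMENT_PAIRS.get(i, 0) for i in range(256)
)

_UPPER_TABLE = bytes.maketrans(
    bytes(range(ord("a"), ord("z") + 1)),
    bytes(range(ord("A"), ord("Z") + 1)),
)

_VALID = np.zeros(256, dtype=bool)
for _c in IUPAC:
    _VALID[_c] = True

# 2-bit codes for A,C,G,T (alphabet order, so numeric k-mer order is
# lexicographic order); 255 marks every other byte.
CODE2 = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    CODE2[_c] = _i

# 4-bit codes over the full IUPAC alphabet, used for match-finder hashing.
CODE4 = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(IUPAC):
    CODE4[_c] = _i


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the IUPAC nucleotide alphabet."""


def ingest(raw: bytes) -> bytes:
    """Upper-case ``raw`` and verify it only contains IUPAC symbols."""
    seq = raw.translate(_UPPER_TABLE)
    arr = np.frombuffer(seq, dtype=np.uint8)
    if not _VALID[arr].all():
        bad = arr[~_VALID[arr]][0]
        raise AlphabetError(f"invalid symbol {chr(bad)!r} (0x{bad:02x})")
    return seq


def reverse_complement(seq: bytes) -> bytes:
    """Reverse complement over the full IUPAC alphabet."""
    comp = seq.translate(_COMPLEMENT_TABLE)
    if 0 in comp:
        raise AlphabetError("sequence contains a non-IUPAC symbol")
    return comp[::-1]


def canonical_kmer(kmer: bytes) -> bytes:
    """Lexicographically smaller of an ACGT k-mer and its reverse complement."""
    arr = np.frombuffer(kmer, dtype=np.uint8)
    if (CODE2[arr] == 255).any():
        raise AlphabetError("k-mer contains a non-ACGT symbol")
    rc = reverse_complement(kmer)
    return min(kmer, rc)


# ---------------------------------------------------------------------------
# radix packing

_TIERS = (
    (4, 4),   # sigma <= 4  -> 4 symbols/byte, radix 4
    (6, 3),   # sigma <= 6  -> 3 symbols/byte, radix 6
    (16, 2),  # sigma <= 16 -> 2 symbols/byte, radix 16
)


def _tier(sigma: int) -> tuple[int, int]:
    for radix, per_byte in _TIERS:
        if sigma <= radix:
            return radix, per_byte
    return 256, 1


def pack_symbols(seq: bytes) -> tuple[bytes, bytes]:
    """Radix-pack ``seq`` into a payload plus its alphabet descriptor.

    The number of symbols per byte depends on the number of distinct
    symbols sigma in this particular sequence: sigma<=4 packs 4/byte,
    sigma<=6 packs 3/byte, sigma<=16 packs 2/byte.  The descriptor is the
    sorted bytes of the distinct symbols (the symbol-to-code table);
    together with the unpacked length it makes :func:`unpack_symbols`
    exact.
    """
    if not seq:
        return b"", b""
    arr = np.frombuffer(seq, dtype=np.uint8)
    symbols = np.nonzero(np.bincount(arr, minlength=256))[0].astype(np.uint8)
    sigma = len(symbols)
    radix, per_byte = _tier(sigma)
    lut = np.zeros(256, dtype=np.uint8)
    lut[symbols] = np.arange(sigma, dtype=np.uint8)
    codes = lut[arr]
    if per_byte == 1:
        return codes.tobytes(), symbols.tobytes()
    n = len(codes)
    pad = (-n) % per_byte
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    codes = codes.reshape(-1, per_byte).astype(np.uint32)
    weights = radix ** np.arange(per_byte, dtype=np.uint32)
    payload = (codes * weights).sum(axis=1).astype(np.uint8)
    return payload.tobytes(), symbols.tobytes()


def unpack_symbols(payload: bytes, descriptor: bytes, length: int) -> bytes:
    """Inverse of :func:`pack_symbols` given the original length."""
    if length == 0:
        return b""
    symbols = np.frombuffer(descriptor, dtype=np.uint8)
    sigma = len(symbols)
    radix, per_byte = _tier(sigma)
    data = np.frombuffer(payload, dtype=np.uint8)
    if per_byte == 1:
        return symbols[data[:length]].tobytes()
    vals = data.astype(np.uint32)
    cols = []
    for _ in range(per_byte):
        vals, rem = np.divmod(vals, np.uint32(radix))
        cols.append(rem.astype(np.uint8))
    codes = np.stack(cols, axis=1).reshape(-1)[:length]
    return symbols[codes].tobytes()


def packed_size(seq: bytes) -> int:
    """Payload bytes a sequence occupies once radix-packed (no descriptor)."""
    if not seq:
        return 0
    arr = np.frombuffer(seq, dtype=np.uint8)
    sigma = int((np.bincount(arr, minlength=256) > 0).sum())
    _, per_byte = _tier(sigma)
    return -(-len(seq) // per_byte)
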