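"""Greedy LZSS parsing of a segment against a group's reference segment.

A parsed segment is a stream of tokens: literal runs and matches
``(offset, length)`` pointing into the reference.  Matching is seeded by an
index of all ``mmer``-length windows of the reference (hashed with 4-bit
IUPAC codes, so any symbol is indexable) and extended greedily; a match is
emitted only when the extension reaches ``min_match`` bases, otherwise the
position becomes a literal.  On equal lengths the leftmost reference
occurrence wins, making the parse deterministic.

Serialization (pinned; recorded in the archive header):

* literal run  -> ``0x00`` + varint(run length) + raw symbols
* match        -> ``0x01`` + offset as u32 little-endian + varint(length - min_match)
* terminator   -> ``0xFF`` closing one segment description

The match offset is fixed-width on purpose: the serialized cost of a match
then depends only on its length, which makes the division-point objective
(minimize prefix cost against one reference plus suffix cost against
another) decomposable into one forward and one backward pass that are
*exact*, i.e. equal to greedily parsing every prefix and suffix outright.
"""

from __future__ import annotations

import numpy as np

from ._serial import Reader, Writer, varint_size
from .kmers import mmer_values

FLAG_LITERAL = 0x00
FLAG_MATCH = 0x01
TERMINATOR = 0xFF

#: token kinds
LIT = "L"
MATCH = "M"

Token = tuple  # ("L", bytes) | ("M", offset, length)


class CorruptStreamError(ValueError):
    """A serialized token stream is inconsistent with its reference."""


class ReferenceIndex:
    """Position table of all ``mmer``-windows of a reference segment."""

    def __init__(self, ref: bytes, mmer: int) -> None:
        self.ref = ref
        self.mmer = mmer
        self.arr = np.frombuffer(ref, dtype=np.uint8)
        vals = mmer_values(ref, mmer)
        if len(vals) == 0:
            self.unique_vals = np.zeros(0, dtype=np.uint64)
            self.table: dict[int, np.ndarray] = {}
            return
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        breaks = np.nonzero(np.diff(sv))[0] + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [len(sv)]])
        self.unique_vals = sv[starts]
        # positions ascending within each key (stable sort keeps input order)
        self.table = {
            int(sv[s]): order[s:e].astype(np.int64) for s, e in zip(starts, ends)
        }


def _common_len(a: np.ndarray, i: int, b: np.ndarray, p: int, maxl: int) -> int:
    """Length of the common prefix of a[i:] and b[p:], capped at maxl."""
    off = 0
    step = 256
    while off < maxl:
        span = min(step, maxl - off)
        ca = a[i + off : i + off + span]
        cb = b[p + off : p + off + span]
        neq = ca != cb
        if neq.any():
            return off + int(np.argmax(neq))
        off += span
        step = min(step * 4, 1 << 20)
    return maxl


def _query_candidates(seq: bytes, index: ReferenceIndex):
    """m-mer values of seq plus sorted positions where the reference has a hit."""
    qvals = mmer_values(seq, index.mmer)
    uniq = index.unique_vals
    if len(qvals) == 0 or len(uniq) == 0:
        return qvals, np.zeros(0, dtype=np.int64)
    # membership via binary search on the sorted unique values; much
    # cheaper than hashing the query side on every segment
    idx = np.minimum(np.searchsorted(uniq, qvals), len(uniq) - 1)
    return qvals, np.nonzero(uniq[idx] == qvals)[0]


def lzss_parse(seq: bytes, index: ReferenceIndex, min_match: int) -> list[Token]:
    """Greedy left-to-right parse of ``seq`` against the indexed reference."""
    n = len(seq)
    if n == 0:
        return []
    arr = np.frombuffer(seq, dtype=np.uint8)
    ref = index.arr
    qvals, cand_pos = _query_candidates(seq, index)
    tokens: list[Token] = []
    lit_start = 0
    i = 0
    while True:
        nxt = np.searchsorted(cand_pos, i)
        if nxt == len(cand_pos):
            break
        j = int(cand_pos[nxt])
        best_len = 0
        best_pos = -1
        for p in index.table[int(qvals[j])]:
            p = int(p)
            ref_avail = len(ref) - p
            if ref_avail <= best_len:
                break  # positions ascend, so ref_avail only shrinks
            maxl = min(n - j, ref_avail)
            if maxl <= best_len:
                break
            if best_len and ref[p + best_len] != arr[j + best_len]:
                continue
            length = _common_len(arr, j, ref, p, maxl)
            if length > best_len:
                best_len = length
                best_pos = p
        if best_len >= min_match:
            if j > lit_start:
                tokens.append((LIT, seq[lit_start:j]))
            tokens.append((MATCH, best_pos, best_len))
            i = j + best_len
            lit_start = i
        else:
            i = j + 1
        if i >= n:
            break
    if lit_start < n:
        tokens.append((LIT, seq[lit_start:]))
    return tokens


def lzss_decode(tokens: list[Token], ref: bytes) -> bytes:
    """Exact reconstruction of a parsed sequence against its reference."""
    out = bytearray()
    for tok in tokens:
        if tok[0] == LIT:
            out += tok[1]
        else:
            _, p, length = tok
            if p < 0 or length < 0 or p + length > len(ref):
                raise CorruptStreamError(
                    f"match ({p}, {length}) outside reference of {len(ref)} bases"
                )
            out += ref[p : p + length]
    return bytes(out)


def serialize(tokens: list[Token], min_match: int) -> bytes:
    w = Writer()
    for tok in tokens:
        if tok[0] == LIT:
            run = tok[1]
            w.u8(FLAG_LITERAL)
            w.varint(len(run))
            w.raw(run)
        else:
            _, p, length = tok
            w.u8(FLAG_MATCH)
            w.u32(p)
            w.varint(length - min_match)
    w.u8(TERMINATOR)
    return w.getvalue()


def deserialize(buf: bytes, min_match: int) -> list[Token]:
    r = Reader(buf)
    tokens: list[Token] = []
    while True:
        flag = r.u8()
        if flag == TERMINATOR:
            return tokens
        if flag == FLAG_LITERAL:
            tokens.append((LIT, r.blob()))
        elif flag == FLAG_MATCH:
            p = r.u32()
            length = r.varint() + min_match
            tokens.append((MATCH, p, length))
        else:
            raise CorruptStreamError(f"unknown token flag 0x{flag:02x}")


def cost(tokens: list[Token], min_match: int) -> int:
    """Serialized byte length of a token stream (terminator included)."""
    total = 1
    for tok in tokens:
        if tok[0] == LIT:
            r = len(tok[1])
            total += 1 + varint_size(r) + r
        else:
            total += 1 + 4 + varint_size(tok[2] - min_match)
    return total


def parse_cost(seq: bytes, index: ReferenceIndex, min_match: int) -> int:
    return cost(lzss_parse(seq, index, min_match), min_match)


# ---------------------------------------------------------------------------
# division-point machinery

def _vsize(t: np.ndarray) -> np.ndarray:
    """Vectorized varint_size for values < 2^28."""
    return np.where(t < 1 << 7, 1, np.where(t < 1 << 14, 2, np.where(t < 1 << 21, 3, 4)))


def prefix_costs(seq: bytes, index: ReferenceIndex, min_match: int) -> np.ndarray:
    """P[i] = serialized cost of the greedy parse of ``seq[:i]``, for all i.

    Computed from the single full parse: tokens strictly before the cut are
    unchanged; a match cut at t >= min_match bases truncates, a shorter cut
    degenerates into literals merged with any preceding literal run.
    """
    n = len(seq)
    P = np.empty(n + 1, dtype=np.int64)
    P[0] = 1
    tokens = lzss_parse(seq, index, min_match)
    base = 1
    pos = 0
    prev_lit = 0
    for tok in tokens:
        if tok[0] == LIT:
            r = len(tok[1])
            t = np.arange(1, r + 1)
            P[pos + 1 : pos + r + 1] = base + 1 + _vsize(t) + t
            base += 1 + varint_size(r) + r
            prev_lit = r
            pos += r
        else:
            length = tok[2]
            t = np.arange(1, length + 1)
            vals = np.empty(length, dtype=np.int64)
            hi = t >= min_match
            vals[hi] = base + 5 + _vsize(t[hi] - min_match)
            lo = ~hi
            if lo.any():
                tl = t[lo]
                if prev_lit:
                    old = 1 + varint_size(prev_lit) + prev_lit
                    vals[lo] = base - old + 1 + _vsize(prev_lit + tl) + prev_lit + tl
                else:
                    vals[lo] = base + 1 + _vsize(tl) + tl
            P[pos + 1 : pos + length + 1] = vals
            base += 5 + varint_size(length - min_match)
            prev_lit = 0
            pos += length
    return P


def match_lengths(seq: bytes, index: ReferenceIndex) -> np.ndarray:
    """Longest reference match starting at every position of ``seq``.

    Forward scan with the classic bound l(i) >= l(i-1) - 1 (drop the first
    base of the previous best match); index candidates are probed with a
    one-byte rejection test before full extension.
    """
    n = len(seq)
    out = np.zeros(n, dtype=np.int64)
    if n == 0:
        return out
    arr = np.frombuffer(seq, dtype=np.uint8)
    ref = index.arr
    qvals, cand_pos = _query_candidates(seq, index)
    is_cand = np.zeros(n, dtype=bool)
    is_cand[cand_pos] = True
    prev = 0
    for i in range(n):
        best = prev - 1 if prev > 0 else 0
        avail = n - i
        if best > avail:
            best = avail
        if avail > best and i < len(qvals) and is_cand[i]:
            for p in index.table[int(qvals[i])]:
                p = int(p)
                ref_avail = len(ref) - p
                if ref_avail <= best:
                    break
                maxl = min(avail, ref_avail)
                if maxl <= best:
                    break
                if best and ref[p + best] != arr[i + best]:
                    continue
                length = _common_len(arr, i, ref, p, maxl)
                if length > best:
                    best = length
        out[i] = best
        prev = best
    return out


def suffix_costs(seq: bytes, index: ReferenceIndex, min_match: int) -> np.ndarray:
    """C[i] = serialized cost of the greedy parse of ``seq[i:]``, for all i.

    Backward dynamic program over the longest-match array: greedy parsing
    of a suffix is the token at its head plus the greedy parse of the rest,
    with literal-run accounting for heads shorter than ``min_match``.
    """
    n = len(seq)
    C = np.empty(n + 1, dtype=np.int64)
    C[n] = 1
    if n == 0:
        return C
    lengths = match_lengths(seq, index)
    run = np.zeros(n + 1, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        l = int(lengths[i])
        if l >= min_match:
            C[i] = C[i + l] + 5 + varint_size(l - min_match)
            run[i] = 0
        else:
            r = int(run[i + 1]) + 1
            run[i] = r
            C[i] = C[i + r] + 1 + varint_size(r) + r
    return C


def find_division_point(
    seg: bytes, ref_a: bytes, ref_b: bytes, min_match: int, mmer: int
) -> int:
    """Index i minimizing cost(parse(seg[:i], ref_a)) + cost(parse(seg[i:], ref_b)).

    Ties break toward the smallest i.  Used when a segment spans a splitter
    pair with no group of its own but two flanking groups exist.
    """
    P = prefix_costs(seg, ReferenceIndex(ref_a, mmer), min_match)
    C = suffix_costs(seg, ReferenceIndex(ref_b, mmer), min_match)
    return int(np.argmin(P + C))
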