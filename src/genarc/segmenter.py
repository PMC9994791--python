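"""Stage 3: split contigs at splitter occurrences and place segments in groups.

A contig is cut at every position whose canonical k-mer is a registered
splitter; the splitter's k bases belong to both neighboring segments, so
consecutive segments overlap by k.  Segments carry 2, 1 or 0 terminating
splitters (spt-2 / spt-1 / spt-0) and are normalized so the splitter with
the smaller canonical form sits at the front, which makes group identity
strand-free.

Placement rules:

* spt-2: the (front, back) splitter pair identifies the group.  If no such
  group exists but groups (s1, s3) and (s3, s2) do for some splitter s3,
  the s3 splitter is taken to be missing from this haplotype and the
  segment is divided at the cost-optimal point into two one-splitter
  members of those groups (abutting, overlap 0 at the junction).
  Otherwise the segment founds a new group and becomes its reference.
* spt-1: every group whose key mentions the splitter is scored by LZSS
  cost (both orientations); the segment joins the cheapest group if that
  costs less than ``spt1_join_threshold`` times the raw packed segment,
  else it founds a single-splitter group.
* spt-0: strand-canonicalized (lexicographically smaller of the sequence
  and its reverse complement) and distributed by a pinned content hash
  (blake2b-64) into one of 16 buckets; the first arrival is the bucket
  reference.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .lzss import (
    ReferenceIndex,
    Token,
    cost,
    lzss_parse,
    prefix_costs,
    suffix_costs,
)
from .model import Params
from .sequence import packed_size, reverse_complement
from .splitters import SplitterSet

N_BUCKETS = 16

#: fixed bytes a brand-new group costs beyond its packed reference payload
#: (zstd frame header plus its directory entry); part of the raw-storage
#: cost a candidate group must undercut for an spt-1 segment to join
NEW_GROUP_OVERHEAD = 32

SPT2 = "spt-2"
SPT1 = "spt-1"
SPT0 = "spt-0"


@dataclass
class Segment:
    """A contig slice with 0-2 terminating splitters.

    ``left``/``right`` are splitter ids at the segment's ends in its
    *current* orientation; ``is_rc`` records whether that orientation
    differs from the contig's; ``overlap`` is the number of bases shared
    with the previous segment of the contig (k, or 0 for the first segment
    and at missing-splitter junctions).
    """

    seq: bytes
    left: int | None
    right: int | None
    is_rc: bool = False
    overlap: int = 0

    @property
    def kind(self) -> str:
        n = (self.left is not None) + (self.right is not None)
        return (SPT0, SPT1, SPT2)[n]


def split_contig(
    contig: bytes, splitters: SplitterSet, params: Params
) -> list[Segment]:
    """Cut a contig at every splitter occurrence (splitter in both sides)."""
    k = params.k
    if len(contig) < k or len(splitters) == 0:
        return [Segment(contig, None, None)]
    from .kmers import canonical_scan

    vals, valid = canonical_scan(contig, k)
    ids = splitters.lookup_many(vals)
    ids[~valid] = -1
    positions = np.nonzero(ids >= 0)[0]
    if len(positions) == 0:
        return [Segment(contig, None, None)]
    segments: list[Segment] = []
    prev_pos: int | None = None
    prev_id: int | None = None
    for p in positions:
        p = int(p)
        sid = int(ids[p])
        if prev_pos is None:
            segments.append(Segment(contig[: p + k], None, sid))
        else:
            segments.append(
                Segment(contig[prev_pos : p + k], prev_id, sid, overlap=k)
            )
        prev_pos, prev_id = p, sid
    segments.append(Segment(contig[prev_pos:], prev_id, None, overlap=k))
    return segments


def reconstruct_contig(segments: list[Segment]) -> bytes:
    """Undo orientation flips, drop overlaps, concatenate."""
    parts = []
    for seg in segments:
        seq = reverse_complement(seg.seq) if seg.is_rc else seg.seq
        parts.append(seq[seg.overlap :])
    return b"".join(parts)


def _flip(seg: Segment) -> Segment:
    return Segment(
        reverse_complement(seg.seq),
        left=seg.right,
        right=seg.left,
        is_rc=not seg.is_rc,
        overlap=seg.overlap,
    )


def normalize_segment(seg: Segment, splitters: SplitterSet) -> Segment:
    """Bring the lexicographically smaller canonical splitter to the front.

    spt-1 segments get their single splitter to the front; equal canonical
    forms (same splitter at both ends) break the tie by the smaller whole
    sequence.  spt-0 segments are returned unchanged.  Idempotent.
    """
    kind = seg.kind
    if kind == SPT0:
        return seg
    if kind == SPT1:
        return _flip(seg) if seg.left is None else seg
    cl = splitters.value_of(seg.left)
    cr = splitters.value_of(seg.right)
    if cr < cl:
        return _flip(seg)
    if cl == cr and reverse_complement(seg.seq) < seg.seq:
        return _flip(seg)
    return seg


def spt0_bucket(seq: bytes) -> int:
    """Deterministic bucket 0..15 from the strand-canonical sequence."""
    canon = min(seq, reverse_complement(seq))
    digest = hashlib.blake2b(canon, digest_size=8).digest()
    return int.from_bytes(digest, "little") % N_BUCKETS


@dataclass
class Placement:
    """Where one stored segment goes: group, stored bytes and bookkeeping.

    ``tokens`` is ``None`` when the segment becomes the group's reference
    (stored packed, not parsed).
    """

    gid: int
    stored_seq: bytes
    is_rc: bool
    overlap: int
    tokens: list[Token] | None

    @property
    def length(self) -> int:
        return len(self.stored_seq)


class GroupRegistry:
    """In-memory directory of groups and the placement logic.

    ``ref_provider(gid)`` returns the group's reference sequence; during
    creation it reads the builder's in-memory store, after reopening it
    decompresses the reference frame on demand.
    """

    def __init__(
        self,
        splitters: SplitterSet,
        params: Params,
        ref_provider: Callable[[int], bytes],
    ) -> None:
        self.splitters = splitters
        self.params = params
        self.ref_provider = ref_provider
        self.kinds: list[str] = []
        self.keys: list[tuple[int, ...]] = []
        self.pair_map: dict[tuple[int, int], int] = {}
        self.single_map: dict[int, int] = {}
        self.bucket_map: dict[int, int] = {}
        self.containing: dict[int, list[int]] = {}
        self.partners: dict[int, dict[int, int]] = {}
        self._indices: dict[int, ReferenceIndex] = {}

    # -- directory -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.kinds)

    def register(self, kind: str, key: tuple[int, ...]) -> int:
        """Add a group to the directory (used both live and when reloading)."""
        gid = len(self.kinds)
        self.kinds.append(kind)
        self.keys.append(key)
        if kind == "pair":
            s1, s2 = key
            self.pair_map[(s1, s2)] = gid
            self.partners.setdefault(s1, {})[s2] = gid
            self.partners.setdefault(s2, {})[s1] = gid
            self.containing.setdefault(s1, []).append(gid)
            if s2 != s1:
                self.containing.setdefault(s2, []).append(gid)
        elif kind == "single":
            (s,) = key
            self.single_map[s] = gid
            self.containing.setdefault(s, []).append(gid)
        else:
            (idx,) = key
            self.bucket_map[idx] = gid
        return gid

    def index_of(self, gid: int) -> ReferenceIndex:
        idx = self._indices.get(gid)
        if idx is None:
            idx = ReferenceIndex(self.ref_provider(gid), self.params.mmer)
            self._indices[gid] = idx
        return idx

    # -- placement -----------------------------------------------------

    def place(self, seg: Segment) -> list[Placement]:
        seg = normalize_segment(seg, self.splitters)
        kind = seg.kind
        if kind == SPT2:
            return self._place_spt2(seg)
        if kind == SPT1:
            return [self._place_spt1(seg)]
        return [self._place_spt0(seg)]

    def _ordered_pair(self, a: int, b: int) -> tuple[int, int]:
        va = self.splitters.value_of(a)
        vb = self.splitters.value_of(b)
        return (a, b) if (va, a) <= (vb, b) else (b, a)

    def _place_spt2(self, seg: Segment) -> list[Placement]:
        key = (seg.left, seg.right)
        gid = self.pair_map.get(key)
        if gid is not None:
            tokens = lzss_parse(seg.seq, self.index_of(gid), self.params.min_match)
            return [Placement(gid, seg.seq, seg.is_rc, seg.overlap, tokens)]
        s1, s2 = key
        common = sorted(
            set(self.partners.get(s1, ())) & set(self.partners.get(s2, ()))
        )
        if common:
            return self._divide_spt2(seg, s1, s2, common)
        gid = self.register("pair", key)
        return [Placement(gid, seg.seq, seg.is_rc, seg.overlap, None)]

    def _divide_spt2(
        self, seg: Segment, s1: int, s2: int, candidates: list[int]
    ) -> list[Placement]:
        """Split a missing-splitter segment at the cost-optimal point.

        For each candidate middle splitter s3 the two flanking groups are
        scored with exact prefix/suffix cost passes, in the orientation
        each group stores its members; the cheapest (s3, division point)
        wins, ties toward the smaller s3 id then the smaller index.
        """
        n = len(seg.seq)
        mm = self.params.min_match
        rc_seq: bytes | None = None
        best = None  # (total, s3, i, gidA, gidB, flip1, flip2)
        for s3 in candidates:
            gid_a = self.partners[s1][s3]
            gid_b = self.partners[s3][s2]
            idx_a = self.index_of(gid_a)
            idx_b = self.index_of(gid_b)
            flip1 = self.keys[gid_a][0] != s1
            flip2 = self.keys[gid_b][-1] != s2
            if (flip1 or flip2) and rc_seq is None:
                rc_seq = reverse_complement(seg.seq)
            if flip1:
                # stored prefix is reverse-complemented: its cost is the
                # suffix cost of the reverse complement at n - i
                cost1 = suffix_costs(rc_seq, idx_a, mm)[::-1]
            else:
                cost1 = prefix_costs(seg.seq, idx_a, mm)
            if flip2:
                cost2 = prefix_costs(rc_seq, idx_b, mm)[::-1]
            else:
                cost2 = suffix_costs(seg.seq, idx_b, mm)
            total = cost1 + cost2
            # the contig-first piece must be able to absorb the contig-side
            # overlap, so the division point stays clear of that margin
            lo = 0 if seg.is_rc else seg.overlap
            hi = n - seg.overlap if seg.is_rc else n
            i = lo + int(np.argmin(total[lo : hi + 1]))
            score = int(total[i])
            if best is None or score < best[0]:
                best = (score, s3, i, gid_a, gid_b, flip1, flip2)
        _, _, i, gid_a, gid_b, flip1, flip2 = best
        prefix, suffix = seg.seq[:i], seg.seq[i:]
        stored1 = reverse_complement(prefix) if flip1 else prefix
        stored2 = reverse_complement(suffix) if flip2 else suffix
        tokens1 = lzss_parse(stored1, self.index_of(gid_a), mm)
        tokens2 = lzss_parse(stored2, self.index_of(gid_b), mm)
        pl_a = Placement(gid_a, stored1, seg.is_rc ^ flip1, 0, tokens1)
        pl_b = Placement(gid_b, stored2, seg.is_rc ^ flip2, 0, tokens2)
        # contig order: when the normalized orientation is flipped, the
        # suffix piece comes first in the contig; the contig-side overlap
        # travels with whichever piece is contig-first, the junction gets 0
        ordered = [pl_b, pl_a] if seg.is_rc else [pl_a, pl_b]
        ordered[0].overlap = seg.overlap
        return ordered

    def _place_spt1(self, seg: Segment) -> Placement:
        s = seg.left
        mm = self.params.min_match
        best = None  # (cost, gid, stored_seq, rc_flip, tokens)
        rc_seq: bytes | None = None
        for gid in self.containing.get(s, ()):
            idx = self.index_of(gid)
            tokens_f = lzss_parse(seg.seq, idx, mm)
            cost_f = cost(tokens_f, mm)
            if rc_seq is None:
                rc_seq = reverse_complement(seg.seq)
            tokens_r = lzss_parse(rc_seq, idx, mm)
            cost_r = cost(tokens_r, mm)
            if cost_r < cost_f:
                entry = (cost_r, gid, rc_seq, True, tokens_r)
            else:
                entry = (cost_f, gid, seg.seq, False, tokens_f)
            if best is None or entry[0] < best[0]:
                best = entry
        raw = packed_size(seg.seq) + NEW_GROUP_OVERHEAD
        if best is not None and best[0] < self.params.spt1_join_threshold * raw:
            _, gid, stored, flipped, tokens = best
            return Placement(gid, stored, seg.is_rc ^ flipped, seg.overlap, tokens)
        gid = self.register("single", (s,))
        return Placement(gid, seg.seq, seg.is_rc, seg.overlap, None)

    def _place_spt0(self, seg: Segment) -> Placement:
        rc = reverse_complement(seg.seq)
        if rc < seg.seq:
            stored, flipped = rc, True
        else:
            stored, flipped = seg.seq, False
        idx = spt0_bucket(seg.seq)
        gid = self.bucket_map.get(idx)
        if gid is None:
            gid = self.register("bucket", (idx,))
            return Placement(gid, stored, seg.is_rc ^ flipped, seg.overlap, None)
        tokens = lzss_parse(stored, self.index_of(gid), self.params.min_match)
        return Placement(gid, stored, seg.is_rc ^ flipped, seg.overlap, tokens)
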