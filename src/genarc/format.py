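"""On-disk archive layout and metadata codec.

File layout::

    magic "GARC" | u32 version
    zstd frames (group references and blocks, in write order)
    zstd-compressed metadata blob
    footer: u64 metadata offset | u64 metadata compressed size | "CRAG"

Frames are referenced by (offset, compressed size) from the metadata, so
appending can leave every previously written frame untouched: new frames
and a fresh metadata blob are written after the old data region and the
footer is replaced.  A partially filled tail block that gets extended is
rewritten as a new frame; its old frame stays as (small) dead space.

All integers are little-endian; variable-length integers are LEB128.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from numcodecs import Zstd

from ._serial import Reader, Writer
from .model import Params

MAGIC = b"GARC"
FOOTER_MAGIC = b"CRAG"
VERSION = 1
FOOTER_SIZE = 8 + 8 + len(FOOTER_MAGIC)

KIND_CODES = {"pair": 0, "single": 1, "bucket": 2}
KIND_NAMES = {v: k for k, v in KIND_CODES.items()}


class ArchiveFormatError(ValueError):
    """Bad magic, wrong version or a truncated/corrupt file."""


def compress(data: bytes, level: int) -> bytes:
    return bytes(Zstd(level=level).encode(data))


def decompress(data: bytes) -> bytes:
    return bytes(Zstd().decode(data))


@dataclass
class BlockMeta:
    offset: int
    csize: int
    count: int
    desc_lens: list[int]


@dataclass
class GroupMeta:
    kind: str
    key: tuple[int, ...]
    ref_offset: int
    ref_csize: int
    ref_len: int
    blocks: list[BlockMeta] = field(default_factory=list)

    @property
    def member_count(self) -> int:
        return sum(b.count for b in self.blocks)


@dataclass
class SegRecord:
    gid: int
    seg_id: int
    is_rc: bool
    length: int
    overlap: int


@dataclass
class ContigMeta:
    name: str
    records: list[SegRecord] = field(default_factory=list)


@dataclass
class SampleMeta:
    name: str
    contigs: list[ContigMeta] = field(default_factory=list)


@dataclass
class ArchiveMeta:
    params: Params
    hash_name: str
    splitter_values: np.ndarray  # uint64, id order
    groups: list[GroupMeta]
    samples: list[SampleMeta]


def write_meta(meta: ArchiveMeta) -> bytes:
    w = Writer()
    p = meta.params
    w.varint(p.k)
    w.varint(p.segment_size)
    w.varint(p.block_size)
    w.u8(1 if p.adaptive else 0)
    w.varint(p.min_match)
    w.varint(p.mmer)
    w.varint(p.zstd_level)
    w.raw(struct.pack("<d", p.spt1_join_threshold))
    w.string(meta.hash_name)
    w.varint(len(meta.splitter_values))
    w.raw(np.asarray(meta.splitter_values, dtype="<u8").tobytes())
    w.varint(len(meta.groups))
    for g in meta.groups:
        w.u8(KIND_CODES[g.kind])
        w.varint(len(g.key))
        for kid in g.key:
            w.varint(kid)
        w.varint(g.ref_offset)
        w.varint(g.ref_csize)
        w.varint(g.ref_len)
        w.varint(len(g.blocks))
        for b in g.blocks:
            w.varint(b.offset)
            w.varint(b.csize)
            w.varint(b.count)
            for dl in b.desc_lens:
                w.varint(dl)
    w.varint(len(meta.samples))
    for s in meta.samples:
        w.string(s.name)
        w.varint(len(s.contigs))
        for c in s.contigs:
            w.string(c.name)
            w.varint(len(c.records))
            for r in c.records:
                w.varint(r.gid)
                w.varint(r.seg_id)
                w.u8(1 if r.is_rc else 0)
                w.varint(r.length)
                w.varint(r.overlap)
    return w.getvalue()


def read_meta(blob: bytes) -> ArchiveMeta:
    r = Reader(blob)
    k = r.varint()
    segment_size = r.varint()
    block_size = r.varint()
    adaptive = bool(r.u8())
    min_match = r.varint()
    mmer = r.varint()
    zstd_level = r.varint()
    (threshold,) = struct.unpack("<d", r.raw(8))
    params = Params(
        k=k,
        segment_size=segment_size,
        block_size=block_size,
        adaptive=adaptive,
        min_match=min_match,
        mmer=mmer,
        zstd_level=zstd_level,
        spt1_join_threshold=threshold,
    )
    hash_name = r.string()
    n_split = r.varint()
    splitter_values = np.frombuffer(r.raw(8 * n_split), dtype="<u8").astype(np.uint64)
    groups = []
    for _ in range(r.varint()):
        kind = KIND_NAMES[r.u8()]
        key = tuple(r.varint() for _ in range(r.varint()))
        ref_offset = r.varint()
        ref_csize = r.varint()
        ref_len = r.varint()
        g = GroupMeta(kind, key, ref_offset, ref_csize, ref_len)
        for _ in range(r.varint()):
            offset = r.varint()
            csize = r.varint()
            count = r.varint()
            desc_lens = [r.varint() for _ in range(count)]
            g.blocks.append(BlockMeta(offset, csize, count, desc_lens))
        groups.append(g)
    samples = []
    for _ in range(r.varint()):
        s = SampleMeta(r.string())
        for _ in range(r.varint()):
            c = ContigMeta(r.string())
            for _ in range(r.varint()):
                gid = r.varint()
                seg_id = r.varint()
                is_rc = bool(r.u8())
                length = r.varint()
                overlap = r.varint()
                c.records.append(SegRecord(gid, seg_id, is_rc, length, overlap))
            s.contigs.append(c)
        samples.append(s)
    return ArchiveMeta(params, hash_name, splitter_values, groups, samples)


def pack_reference_frame(seq: bytes, level: int) -> bytes:
    """Self-contained compressed blob of a group reference segment."""
    from .sequence import pack_symbols

    payload, descriptor = pack_symbols(seq)
    w = Writer()
    w.blob(descriptor)
    w.raw(payload)
    return compress(w.getvalue(), level)


def unpack_reference_frame(frame: bytes, seq_len: int) -> bytes:
    from .sequence import unpack_symbols

    blob = decompress(frame)
    r = Reader(blob)
    descriptor = r.blob()
    payload = blob[r.pos :]
    return unpack_symbols(payload, descriptor, seq_len)


def read_footer(fh) -> tuple[int, int]:
    """Return (metadata offset, metadata compressed size) of an archive file."""
    fh.seek(0)
    head = fh.read(8)
    if len(head) < 8 or head[:4] != MAGIC:
        raise ArchiveFormatError("not a genarc archive (bad magic)")
    (version,) = struct.unpack("<I", head[4:8])
    if version != VERSION:
        raise ArchiveFormatError(f"unsupported archive version {version}")
    fh.seek(0, 2)
    size = fh.tell()
    if size < 8 + FOOTER_SIZE:
        raise ArchiveFormatError("truncated archive")
    fh.seek(size - FOOTER_SIZE)
    footer = fh.read(FOOTER_SIZE)
    if footer[16:] != FOOTER_MAGIC:
        raise ArchiveFormatError("truncated archive (bad footer)")
    meta_off, meta_csize = struct.unpack("<QQ", footer[:16])
    if meta_off + meta_csize > size:
        raise ArchiveFormatError("corrupt footer offsets")
    return meta_off, meta_csize
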