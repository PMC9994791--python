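"""Archive construction: create, add genomes, seal, append.

The builder keeps new group references and token-stream blocks in memory
and writes zstd frames at seal time.  Appending reopens an existing file,
reconstructs the group directory from the metadata, and loads a group's
partially filled tail block only when a new member actually lands in that
group; previously sealed frames are never rewritten.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import struct

import numpy as np

from . import adaptive
from .format import (
    FOOTER_MAGIC,
    MAGIC,
    VERSION,
    ArchiveMeta,
    BlockMeta,
    ContigMeta,
    GroupMeta,
    SampleMeta,
    SegRecord,
    compress,
    decompress,
    pack_reference_frame,
    read_footer,
    read_meta,
    unpack_reference_frame,
    write_meta,
)
from .lzss import serialize
from .model import Genome, Params
from .segmenter import SPT0, GroupRegistry, split_contig
from .sequence import ingest
from .splitters import SplitterSet, determine_splitters, reference_kmer_census

HASH_NAME = "blake2b-64"


class DuplicateSampleError(ValueError):
    """A sample with this name is already present in the archive."""


@dataclass
class _Block:
    """A block of member descriptions; ``offset`` is None until written."""

    descs: list[bytes] = field(default_factory=list)
    offset: int | None = None
    csize: int = 0

    @property
    def count(self) -> int:
        return len(self.descs)

    @property
    def desc_lens(self) -> list[int]:
        return [len(d) for d in self.descs]


@dataclass
class _DiskBlock:
    """A block already on disk whose descriptions were not loaded."""

    offset: int
    csize: int
    count: int
    desc_lens: list[int]


@dataclass
class _Group:
    kind: str
    key: tuple[int, ...]
    ref_seq: bytes | None = None
    ref_len: int = 0
    ref_offset: int | None = None
    ref_csize: int = 0
    blocks: list = field(default_factory=list)
    open_descs: list[bytes] = field(default_factory=list)
    member_count: int = 0


class ArchiveBuilder:
    """Open archive being created or extended.

    Use :meth:`create` / :meth:`open_for_append`, then :meth:`add_genome`
    for each sample and finally :meth:`seal_and_write`.
    """

    def __init__(self, path: str, params: Params, splitters: SplitterSet) -> None:
        self.path = str(path)
        self.params = params
        self.splitters = splitters
        self.groups: list[_Group] = []
        self.samples: list[SampleMeta] = []
        self.registry = GroupRegistry(splitters, params, self._ref_seq)
        self._fresh = True
        self._meta_offset: int | None = None
        self._ref_kmers: np.ndarray | None = None  # adaptive: all reference k-mers

    # -- construction entry points -------------------------------------

    @classmethod
    def create(cls, path: str, reference: Genome, params: Params | None = None):
        """Run stages 1-2 on the reference and add it as the first sample."""
        params = params or Params()
        uniq, counts = reference_kmer_census(reference, params.k)
        candidates = uniq[counts == 1]
        splitters = determine_splitters(reference, candidates, params)
        builder = cls(path, params, splitters)
        if params.adaptive:
            builder._ref_kmers = uniq
        builder.add_genome(reference)
        return builder

    @classmethod
    def open_for_append(cls, path: str):
        """Reopen an archive; tail blocks are decompressed only when touched."""
        with open(path, "rb") as fh:
            meta_off, meta_csize = read_footer(fh)
            fh.seek(meta_off)
            meta = read_meta(decompress(fh.read(meta_csize)))
        splitters = SplitterSet(meta.params.k)
        for value in meta.splitter_values:
            splitters.add(int(value))
        builder = cls(path, meta.params, splitters)
        builder._fresh = False
        builder._meta_offset = meta_off
        builder.samples = meta.samples
        for gm in meta.groups:
            builder.registry.register(gm.kind, gm.key)
            blocks: list = [
                _DiskBlock(b.offset, b.csize, b.count, b.desc_lens) for b in gm.blocks
            ]
            builder.groups.append(
                _Group(
                    gm.kind,
                    gm.key,
                    ref_seq=None,
                    ref_len=gm.ref_len,
                    ref_offset=gm.ref_offset,
                    ref_csize=gm.ref_csize,
                    blocks=blocks,
                    member_count=gm.member_count,
                )
            )
        if meta.params.adaptive and meta.samples:
            from .reader import ArchiveReader

            with ArchiveReader(path) as reader:
                ref_genome = reader.get_sample(meta.samples[0].name)
            uniq, _ = reference_kmer_census(ref_genome, meta.params.k)
            builder._ref_kmers = uniq
        return builder

    # -- internals -----------------------------------------------------

    def _ref_seq(self, gid: int) -> bytes:
        g = self.groups[gid]
        if g.ref_seq is None:
            with open(self.path, "rb") as fh:
                fh.seek(g.ref_offset)
                frame = fh.read(g.ref_csize)
            g.ref_seq = unpack_reference_frame(frame, g.ref_len)
        return g.ref_seq

    def _ensure_tail_open(self, g: _Group) -> None:
        """Move a partial last block back into the open state for appending."""
        if g.open_descs or not g.blocks:
            return
        last = g.blocks[-1]
        if last.count >= self.params.block_size:
            return
        if isinstance(last, _DiskBlock):
            with open(self.path, "rb") as fh:
                fh.seek(last.offset)
                data = decompress(fh.read(last.csize))
            descs = []
            pos = 0
            for dl in last.desc_lens:
                descs.append(data[pos : pos + dl])
                pos += dl
        else:
            descs = last.descs
        g.blocks.pop()
        g.open_descs = descs

    def _place_contig(self, cm: ContigMeta, segments) -> None:
        for seg in segments:
            for pl in self.registry.place(seg):
                gid = pl.gid
                if gid == len(self.groups):
                    self.groups.append(
                        _Group(
                            self.registry.kinds[gid],
                            self.registry.keys[gid],
                            ref_seq=pl.stored_seq,
                            ref_len=len(pl.stored_seq),
                        )
                    )
                    seg_id = 0
                else:
                    g = self.groups[gid]
                    self._ensure_tail_open(g)
                    g.open_descs.append(serialize(pl.tokens, self.params.min_match))
                    g.member_count += 1
                    seg_id = g.member_count
                    if len(g.open_descs) >= self.params.block_size:
                        g.blocks.append(_Block(descs=g.open_descs))
                        g.open_descs = []
                cm.records.append(
                    SegRecord(gid, seg_id, pl.is_rc, pl.length, pl.overlap)
                )

    # -- public API ----------------------------------------------------

    def add_genome(self, genome: Genome) -> None:
        """Segment, place and encode every contig of a sample."""
        if any(s.name == genome.name for s in self.samples):
            raise DuplicateSampleError(
                f"sample {genome.name!r} is already in the archive"
            )
        is_first = not self.samples
        sm = SampleMeta(genome.name)
        self.samples.append(sm)
        buffered: list[tuple[ContigMeta, bytes]] = []
        for cname, raw in genome.contigs:
            seq = ingest(raw)
            cm = ContigMeta(cname)
            sm.contigs.append(cm)
            if not seq:
                continue
            segments = split_contig(seq, self.splitters, self.params)
            if (
                self.params.adaptive
                and not is_first
                and len(segments) == 1
                and segments[0].kind == SPT0
                and len(seq) >= self.params.k
            ):
                buffered.append((cm, seq))
                continue
            self._place_contig(cm, segments)
        if buffered:
            adaptive.extend_splitters_from_buffer(
                [seq for _, seq in buffered],
                self._ref_kmers,
                self.splitters,
                self.params,
            )
            for cm, seq in buffered:
                self._place_contig(cm, split_contig(seq, self.splitters, self.params))

    def seal_and_write(self) -> None:
        """Flush open blocks, write new frames, metadata and footer."""
        level = self.params.zstd_level
        for g in self.groups:
            if g.open_descs:
                g.blocks.append(_Block(descs=g.open_descs))
                g.open_descs = []
        if self._fresh:
            fh = open(self.path, "wb")
            fh.write(MAGIC + struct.pack("<I", VERSION))
        else:
            fh = open(self.path, "r+b")
            fh.truncate(self._meta_offset)
            fh.seek(self._meta_offset)
        try:
            for g in self.groups:
                if g.ref_offset is None:
                    frame = pack_reference_frame(g.ref_seq, level)
                    g.ref_offset = fh.tell()
                    g.ref_csize = len(frame)
                    fh.write(frame)
                for b in g.blocks:
                    if isinstance(b, _Block) and b.offset is None:
                        frame = compress(b"".join(b.descs), level)
                        b.offset = fh.tell()
                        b.csize = len(frame)
                        fh.write(frame)
            meta = ArchiveMeta(
                params=self.params,
                hash_name=HASH_NAME,
                splitter_values=np.array(self.splitters.values, dtype=np.uint64),
                groups=[
                    GroupMeta(
                        g.kind,
                        g.key,
                        g.ref_offset,
                        g.ref_csize,
                        g.ref_len,
                        [
                            BlockMeta(b.offset, b.csize, b.count, b.desc_lens)
                            for b in g.blocks
                        ],
                    )
                    for g in self.groups
                ],
                samples=self.samples,
            )
            blob = compress(write_meta(meta), level)
            self._meta_offset = fh.tell()
            fh.write(blob)
            fh.write(struct.pack("<QQ", self._meta_offset, len(blob)) + FOOTER_MAGIC)
        finally:
            fh.close()
        self._fresh = False


def build_archive(
    path: str,
    reference: Genome,
    samples=(),
    params: Params | None = None,
) -> str:
    """Create an archive from a reference plus samples and seal it."""
    builder = ArchiveBuilder.create(path, reference, params)
    for genome in samples:
        builder.add_genome(genome)
    builder.seal_and_write()
    return str(path)


def append_archive(path: str, samples) -> str:
    """Add samples to an existing archive in place."""
    builder = ArchiveBuilder.open_for_append(path)
    for genome in samples:
        builder.add_genome(genome)
    builder.seal_and_write()
    return str(path)
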