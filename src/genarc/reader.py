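"""Random-access decompression of archives.

Only the frames needed for a query are decompressed: the contig
description names the groups and in-group segment ids, each segment pulls
in its group's reference frame and (for non-reference members) the one
block frame containing its description.  Decompressed frames are cached
per reader; ``frames_touched`` counts actual frame decompressions and
``bytes_decompressed`` their uncompressed sizes, so access locality can be
asserted with a freshly opened (or counter-reset) reader.

Internal coordinates are 0-based half-open; the CLI layer translates the
samtools-style 1-based inclusive ``contig:FROM-TO`` syntax.
"""

from __future__ import annotations

import os

from ._serial import Reader as _BinReader
from .format import decompress, read_footer, read_meta
from .lzss import deserialize, lzss_decode
from .model import Genome
from .sequence import reverse_complement, unpack_symbols


class UnknownItemError(KeyError):
    """Sample or contig not present; message suggests near-miss names."""


class RangeError(ValueError):
    """Requested interval falls outside the contig."""


def _edit_distance(a: str, b: str, limit: int = 3) -> int:
    if abs(len(a) - len(b)) > limit:
        return limit + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        if min(cur) > limit:
            return limit + 1
        prev = cur
    return prev[-1]


def _not_found(kind: str, name: str, known) -> UnknownItemError:
    close = [n for n in known if _edit_distance(n, name, 2) <= 2]
    msg = f"unknown {kind} {name!r}"
    if close:
        msg += "; did you mean " + ", ".join(repr(n) for n in sorted(close)[:3]) + "?"
    return UnknownItemError(msg)


class ArchiveReader:
    """Read-only random-access view of an archive file."""

    def __init__(self, path: str) -> None:
        self.path = str(path)
        self._fh = open(path, "rb")
        meta_off, meta_csize = read_footer(self._fh)
        self._fh.seek(meta_off)
        self.meta = read_meta(decompress(self._fh.read(meta_csize)))
        self.params = self.meta.params
        self._meta_offset = meta_off
        self._meta_csize = meta_csize
        self._samples = {s.name: s for s in self.meta.samples}
        self._frame_cache: dict[int, bytes] = {}
        self._ref_cache: dict[int, bytes] = {}
        self.frames_touched = 0
        self.bytes_decompressed = 0

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc) -> bool:
        self.close()
        return False

    def reset_counters(self) -> None:
        """Zero the instrumentation counters and drop the frame caches."""
        self.frames_touched = 0
        self.bytes_decompressed = 0
        self._frame_cache.clear()
        self._ref_cache.clear()

    # -- frame access --------------------------------------------------

    def _frame(self, offset: int, csize: int) -> bytes:
        data = self._frame_cache.get(offset)
        if data is None:
            self._fh.seek(offset)
            data = decompress(self._fh.read(csize))
            self._frame_cache[offset] = data
            self.frames_touched += 1
            self.bytes_decompressed += len(data)
        return data

    def group_reference(self, gid: int) -> bytes:
        seq = self._ref_cache.get(gid)
        if seq is None:
            g = self.meta.groups[gid]
            blob = self._frame(g.ref_offset, g.ref_csize)
            r = _BinReader(blob)
            descriptor = r.blob()
            seq = unpack_symbols(blob[r.pos :], descriptor, g.ref_len)
            self._ref_cache[gid] = seq
        return seq

    def _member(self, gid: int, seg_id: int) -> bytes:
        """Stored (normalized-orientation) bytes of one segment."""
        if seg_id == 0:
            return self.group_reference(gid)
        g = self.meta.groups[gid]
        target = seg_id - 1
        cum = 0
        for b in g.blocks:
            if target < cum + b.count:
                data = self._frame(b.offset, b.csize)
                idx = target - cum
                start = sum(b.desc_lens[:idx])
                desc = data[start : start + b.desc_lens[idx]]
                tokens = deserialize(desc, self.params.min_match)
                return lzss_decode(tokens, self.group_reference(gid))
            cum += b.count
        raise ValueError(f"segment {seg_id} missing from group {gid}")

    # -- queries -------------------------------------------------------

    def _sample_meta(self, sample: str):
        sm = self._samples.get(sample)
        if sm is None:
            raise _not_found("sample", sample, self._samples)
        return sm

    def _contig_meta(self, sample: str, contig: str):
        sm = self._sample_meta(sample)
        for cm in sm.contigs:
            if cm.name == contig:
                return cm
        raise _not_found(
            f"contig in sample {sample!r}", contig, [c.name for c in sm.contigs]
        )

    def contig_length(self, sample: str, contig: str) -> int:
        cm = self._contig_meta(sample, contig)
        return sum(r.length - r.overlap for r in cm.records)

    def get_contig(
        self,
        sample: str,
        contig: str,
        start: int | None = None,
        end: int | None = None,
    ) -> bytes:
        """One contig, optionally restricted to [start, end) (0-based)."""
        cm = self._contig_meta(sample, contig)
        total = sum(r.length - r.overlap for r in cm.records)
        if start is None:
            start, end = 0, total
        if end is None:
            end = total
        if not (0 <= start <= end <= total):
            raise RangeError(
                f"range [{start}, {end}) outside contig of length {total}"
            )
        if start == end:
            return b""
        parts = []
        pos = 0
        for r in cm.records:
            contrib = r.length - r.overlap
            lo = max(start, pos)
            hi = min(end, pos + contrib)
            if lo < hi:
                stored = self._member(r.gid, r.seg_id)
                if r.is_rc:
                    stored = reverse_complement(stored)
                piece = stored[r.overlap :]
                parts.append(piece[lo - pos : hi - pos])
            pos += contrib
            if pos >= end:
                break
        return b"".join(parts)

    def get_sample(self, sample: str) -> Genome:
        sm = self._sample_meta(sample)
        return Genome(
            sm.name, [(c.name, self.get_contig(sm.name, c.name)) for c in sm.contigs]
        )

    def get_collection(self) -> list[Genome]:
        return [self.get_sample(s.name) for s in self.meta.samples]

    def find_contig(self, contig: str) -> list[str]:
        """Names of samples containing a contig with this name."""
        return [
            s.name
            for s in self.meta.samples
            if any(c.name == contig for c in s.contigs)
        ]

    # -- listings and statistics ---------------------------------------

    def list_samples(self) -> list[str]:
        return [s.name for s in self.meta.samples]

    def list_contigs(self) -> list[tuple[str, str]]:
        return [(s.name, c.name) for s in self.meta.samples for c in s.contigs]

    def info(self) -> dict:
        kinds = {"pair": 0, "single": 0, "bucket": 0}
        blocks = 0
        members = 0
        bucket_segments = 0
        for g in self.meta.groups:
            kinds[g.kind] += 1
            blocks += len(g.blocks)
            members += g.member_count
            if g.kind == "bucket":
                bucket_segments += 1 + g.member_count
        return {
            "samples": len(self.meta.samples),
            "contigs": sum(len(s.contigs) for s in self.meta.samples),
            "splitters": len(self.meta.splitter_values),
            "groups": {**kinds, "total": len(self.meta.groups)},
            "blocks": blocks,
            "segments": members + len(self.meta.groups),
            "spt0_segments": bucket_segments,
            "params": {
                "k": self.params.k,
                "segment_size": self.params.segment_size,
                "block_size": self.params.block_size,
                "adaptive": self.params.adaptive,
            },
            "file_size": os.path.getsize(self.path),
            "data_bytes": self._meta_offset - 8,
            "metadata_compressed": self._meta_csize,
        }
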