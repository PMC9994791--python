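"""Stages 1 and 2 of compression: candidate k-mers and splitter selection.

Candidate k-mers are the canonical k-mers that occur exactly once across
all reference contigs (counting canonical forms, so a k-mer and its
reverse complement are one entity).  Splitters are candidates picked
during a spaced left-to-right walk of each reference contig: record the
first candidate occurrence, resume scanning ``segment_size`` bases after
its start, and finally add the last candidate occurrence of the contig.
"""

from __future__ import annotations

import warnings

import numpy as np

from .kmers import canonical_scan
from .model import Genome, Params


class SplitterSet:
    """Ordered registry of splitter k-mers (canonical 2-bit values).

    Ids are assigned in insertion order and never reused; adaptive mode
    appends to the registry.  Membership queries are vectorized against a
    sorted snapshot that is rebuilt lazily after insertions.
    """

    def __init__(self, k: int) -> None:
        self.k = k
        self.values: list[int] = []          # id -> canonical value
        self._id_of: dict[int, int] = {}     # canonical value -> id
        self._sorted: np.ndarray | None = None
        self._sorted_ids: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, value: int) -> bool:
        return int(value) in self._id_of

    def id_of(self, value: int) -> int:
        return self._id_of[int(value)]

    def value_of(self, sid: int) -> int:
        return self.values[sid]

    def add(self, value: int) -> int:
        """Register a canonical k-mer value; return its id (existing or new)."""
        value = int(value)
        sid = self._id_of.get(value)
        if sid is None:
            sid = len(self.values)
            self.values.append(value)
            self._id_of[value] = sid
            self._sorted = None
        return sid

    def _snapshot(self) -> tuple[np.ndarray, np.ndarray]:
        if self._sorted is None:
            vals = np.array(self.values, dtype=np.uint64)
            order = np.argsort(vals, kind="stable")
            self._sorted = vals[order]
            self._sorted_ids = order.astype(np.int64)
        return self._sorted, self._sorted_ids

    def lookup_many(self, values: np.ndarray) -> np.ndarray:
        """Map canonical values to splitter ids (-1 where absent)."""
        out = np.full(len(values), -1, dtype=np.int64)
        if not self.values or len(values) == 0:
            return out
        svals, sids = self._snapshot()
        idx = np.searchsorted(svals, values)
        idx_c = np.minimum(idx, len(svals) - 1)
        hit = svals[idx_c] == values
        out[hit] = sids[idx_c[hit]]
        return out


def kmer_census(seqs, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer census over an iterable of sequences.

    Returns ``(unique_values, counts)`` over all valid windows; both arrays
    sorted by value.
    """
    chunks = []
    for seq in seqs:
        vals, valid = canonical_scan(seq, k)
        if len(vals):
            chunks.append(vals[valid])
    if not chunks:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=np.int64)
    return np.unique(np.concatenate(chunks), return_counts=True)


def reference_kmer_census(genome: Genome, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer census of a genome (all contigs pooled)."""
    return kmer_census((seq for _, seq in genome.contigs), k)


def find_candidate_kmers(genome: Genome, k: int) -> np.ndarray:
    """Canonical k-mers occurring exactly once in the reference (sorted)."""
    uniq, counts = reference_kmer_census(genome, k)
    if len(uniq) == 0:
        warnings.warn("reference contains no valid k-mers", stacklevel=2)
    return uniq[counts == 1]


def determine_splitters(
    genome: Genome, candidates: np.ndarray, params: Params
) -> SplitterSet:
    """Spaced walk over reference contigs selecting splitters.

    Per contig: take the first candidate occurrence at position p, resume
    the scan at ``p + segment_size``, repeat; the last candidate occurrence
    of the contig is also a splitter.  The result is deduplicated by
    canonical form with ids in insertion order.
    """
    splitters = SplitterSet(params.k)
    for _, seq in genome.contigs:
        for value in _walk_contig(seq, candidates, params.k, params.segment_size):
            splitters.add(value)
    return splitters


def _candidate_positions(
    seq: bytes, candidates: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """(window values, positions of candidate occurrences) in one contig."""
    vals, valid = canonical_scan(seq, k)
    if len(vals) == 0 or len(candidates) == 0:
        return vals, np.zeros(0, dtype=np.int64)
    idx = np.searchsorted(candidates, vals)
    idx_c = np.minimum(idx, len(candidates) - 1)
    is_cand = valid & (candidates[idx_c] == vals)
    return vals, np.nonzero(is_cand)[0]


def spaced_walk(positions: np.ndarray, segment_size: int) -> list[int]:
    """Indices selected by the spaced scan plus the final occurrence."""
    if len(positions) == 0:
        return []
    out: list[int] = []
    pos = 0
    while True:
        nxt = np.searchsorted(positions, pos)
        if nxt == len(positions):
            break
        p = int(positions[nxt])
        out.append(p)
        pos = p + segment_size
    last = int(positions[-1])
    if not out or out[-1] != last:
        out.append(last)
    return out


def _walk_contig(
    seq: bytes, candidates: np.ndarray, k: int, segment_size: int
) -> list[int]:
    vals, positions = _candidate_positions(seq, candidates, k)
    return [int(vals[p]) for p in spaced_walk(positions, segment_size)]


def splitter_occurrence_positions(
    seq: bytes, candidates: np.ndarray, k: int, segment_size: int
) -> list[int]:
    """Positions the spaced walk selects in one contig (for diagnostics)."""
    _, positions = _candidate_positions(seq, candidates, k)
    return spaced_walk(positions, segment_size)
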