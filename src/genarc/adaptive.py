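"""Adaptive splitter extension for divergent collections.

In adaptive mode, contigs of an incoming sample that match no splitter at
all (whole-contig spt-0) are buffered rather than stored.  After the
sample's contigs are processed, canonical k-mers that occur exactly once
within the buffer — and are absent from the reference genome (any count)
and from the existing splitter registry — become sample candidates.  The
same spaced walk used on the reference then selects new splitters from the
buffered contigs, the global splitter set is extended, and the buffered
contigs are segmented once more and handled as usual.  Later samples of
the same divergent clade then segment into ordinary spt-2 groups.
"""

from __future__ import annotations

import numpy as np

from .model import Params
from .splitters import SplitterSet, _walk_contig, kmer_census


def sample_candidate_kmers(
    buffered: list[bytes],
    reference_kmers: np.ndarray | None,
    splitters: SplitterSet,
    k: int,
) -> np.ndarray:
    """Canonical k-mers unique in the buffer, new to reference and registry."""
    uniq, counts = kmer_census(buffered, k)
    cand = uniq[counts == 1]
    if reference_kmers is not None and len(reference_kmers) and len(cand):
        cand = cand[~np.isin(cand, reference_kmers)]
    if len(splitters) and len(cand):
        existing = np.sort(np.array(splitters.values, dtype=np.uint64))
        cand = cand[~np.isin(cand, existing)]
    return cand


def extend_splitters_from_buffer(
    buffered: list[bytes],
    reference_kmers: np.ndarray | None,
    splitters: SplitterSet,
    params: Params,
) -> int:
    """Extend the global splitter set from a sample's buffered contigs.

    Returns the number of splitters added.  An empty candidate set leaves
    the buffered contigs to be stored as spt-0.
    """
    cand = sample_candidate_kmers(buffered, reference_kmers, splitters, params.k)
    if len(cand) == 0:
        return 0
    before = len(splitters)
    for seq in buffered:
        for value in _walk_contig(seq, cand, params.k, params.segment_size):
            splitters.add(value)
    return len(splitters) - before
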