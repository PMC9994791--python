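"""Contig segmentation, normalization and group placement."""

import numpy as np
import pytest

from genarc.model import Genome, Params
from genarc.segmenter import (
    SPT0,
    SPT1,
    SPT2,
    GroupRegistry,
    Segment,
    normalize_segment,
    reconstruct_contig,
    split_contig,
    spt0_bucket,
)
from genarc.sequence import reverse_complement
from genarc.splitters import determine_splitters, find_candidate_kmers
from tests.conftest import random_seq


def make_splitters(seq: bytes, params: Params):
    genome = Genome("r", [("c", seq)])
    candidates = find_candidate_kmers(genome, params.k)
    return determine_splitters(genome, candidates, params)


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(42)
    params = Params(k=13, segment_size=1500)
    ref = random_seq(rng, 30_000)
    return rng, params, ref, make_splitters(ref, params)


def test_contig_without_splitters_is_single_spt0(setup):
    _, params, _, splitters = setup
    rng = np.random.default_rng(1)
    contig = random_seq(rng, 500)  # unrelated to reference
    segs = split_contig(contig, splitters, params)
    assert len(segs) == 1 and segs[0].kind == SPT0
    assert segs[0].seq == contig


def test_contig_shorter_than_k_is_spt0(setup):
    _, params, _, splitters = setup
    segs = split_contig(b"ACGT", splitters, params)
    assert [s.kind for s in segs] == [SPT0]


def test_reference_contig_resegments_into_spt1_spt2_chain(setup):
    _, params, ref, splitters = setup
    segs = split_contig(ref, splitters, params)
    kinds = [s.kind for s in segs]
    assert kinds[0] == SPT1 and kinds[-1] == SPT1
    assert all(k == SPT2 for k in kinds[1:-1])
    assert all(s.overlap == params.k for s in segs[1:])
    # interior segments are about one segment_size long
    interior = [len(s.seq) for s in segs[1:-1]]
    assert interior and max(interior) < 3 * params.segment_size
    assert reconstruct_contig(segs) == ref


def test_single_interior_splitter_gives_two_overlapping_spt1(setup):
    _, params, ref, splitters = setup
    rng = np.random.default_rng(2)
    # embed one splitter occurrence inside otherwise foreign sequence
    segs_ref = split_contig(ref, splitters, params)
    splitter_bases = segs_ref[0].seq[-params.k :]
    contig = random_seq(rng, 300) + splitter_bases + random_seq(rng, 300)
    segs = split_contig(contig, splitters, params)
    assert [s.kind for s in segs] == [SPT1, SPT1]
    assert segs[1].overlap == params.k
    assert segs[0].seq[-params.k :] == segs[1].seq[: params.k]
    assert reconstruct_contig(segs) == contig


def test_reconstruction_of_random_mutated_contigs(setup):
    _, params, ref, splitters = setup
    rng = np.random.default_rng(3)
    for _ in range(10):
        # mutate the reference lightly, then check exact reconstruction
        arr = np.frombuffer(ref, dtype=np.uint8).copy()
        pos = rng.integers(0, len(arr), 30)
        arr[pos] = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, 30)]
        contig = arr.tobytes()
        segs = split_contig(contig, splitters, params)
        assert reconstruct_contig(segs) == contig


def test_normalize_is_idempotent_and_orients_splitter_front(setup):
    _, params, ref, splitters = setup
    segs = split_contig(ref, splitters, params)
    for seg in segs:
        norm = normalize_segment(seg, splitters)
        again = normalize_segment(norm, splitters)
        assert (again.seq, again.is_rc) == (norm.seq, norm.is_rc)
        if norm.kind == SPT1:
            assert norm.left is not None
        if norm.kind == SPT2:
            assert splitters.value_of(norm.left) <= splitters.value_of(norm.right)


def test_segment_and_its_rc_normalize_to_same_stored_form(setup):
    _, params, ref, splitters = setup
    segs = split_contig(ref, splitters, params)
    for seg in segs:
        if seg.kind == SPT0:
            continue
        # the same locus read from the opposite strand: a fresh segment
        # whose contig carries the reverse complement
        flipped = Segment(
            reverse_complement(seg.seq),
            left=seg.right,
            right=seg.left,
            is_rc=False,
            overlap=seg.overlap,
        )
        a = normalize_segment(seg, splitters)
        b = normalize_segment(flipped, splitters)
        assert a.seq == b.seq
        assert a.is_rc != b.is_rc


def test_equal_splitter_tiebreak_picks_smaller_sequence(setup):
    _, params, _, splitters = setup
    sid = 0
    # craft a segment with the same splitter at both ends
    from genarc.kmers import value_to_kmer

    kmer = value_to_kmer(splitters.value_of(sid), params.k)
    rng = np.random.default_rng(5)
    middle = random_seq(rng, 100)
    seg = Segment(kmer + middle + kmer, sid, sid, overlap=0)
    norm = normalize_segment(seg, splitters)
    assert norm.seq == min(seg.seq, reverse_complement(seg.seq))


def test_spt0_bucket_deterministic_range_and_spread():
    rng = np.random.default_rng(8)
    buckets = set()
    for _ in range(2000):
        seq = random_seq(rng, 100)
        b = spt0_bucket(seq)
        assert 0 <= b < 16
        assert spt0_bucket(seq) == b
        assert spt0_bucket(reverse_complement(seq)) == b  # strand-free
        buckets.add(b)
    assert buckets == set(range(16))


class _Store:
    """Minimal ref store standing behind a registry in these tests."""

    def __init__(self):
        self.refs = {}

    def provider(self, gid):
        return self.refs[gid]


def place_all(registry, store, segs):
    placements = []
    for seg in segs:
        for pl in registry.place(seg):
            if pl.tokens is None:
                store.refs[pl.gid] = pl.stored_seq
            placements.append(pl)
    return placements


def test_first_genome_creates_groups_and_identical_member_is_one_match(setup):
    _, params, ref, splitters = setup
    store = _Store()
    registry = GroupRegistry(splitters, params, store.provider)
    segs = split_contig(ref, splitters, params)
    first = place_all(registry, store, segs)
    # every segment long enough to LZSS-match founds its own group; tiny
    # boundary tails (shorter than min_match) may join as literal streams
    assert all(
        pl.tokens is None for pl in first if pl.length >= params.min_match
    )
    # identical contig again: every placement is a whole-segment match
    second = place_all(registry, store, split_contig(ref, splitters, params))
    from genarc.lzss import MATCH

    for pl in second:
        if pl.length >= params.min_match:
            assert pl.tokens == [(MATCH, 0, pl.length)]


def test_missing_splitter_divides_into_flanking_groups(setup):
    _, params, ref, splitters = setup
    store = _Store()
    registry = GroupRegistry(splitters, params, store.provider)
    segs = split_contig(ref, splitters, params)
    place_all(registry, store, segs)
    n_groups = len(registry)
    # delete one interior splitter occurrence: concatenate two neighbor
    # segments, dropping the shared splitter's worth of overlap
    a, b = segs[3], segs[4]
    fused = Segment(a.seq + b.seq[params.k :], a.left, b.right, overlap=a.overlap)
    placements = place_all(registry, store, [fused])
    assert len(placements) == 2
    assert len(registry) == n_groups  # no new group was created
    assert placements[0].overlap == fused.overlap and placements[1].overlap == 0
    assert placements[0].length + placements[1].length == len(fused.seq)


def test_spt1_joins_matching_group_else_founds_new(setup):
    _, params, ref, splitters = setup
    store = _Store()
    registry = GroupRegistry(splitters, params, store.provider)
    place_all(registry, store, split_contig(ref, splitters, params))
    rng = np.random.default_rng(9)
    segs = split_contig(ref, splitters, params)
    # a boundary segment identical to an existing reference joins cheaply
    pl = registry.place(segs[0])[0]
    assert pl.tokens is not None
    # a one-splitter segment with foreign tail: splitter known, body alien
    alien = Segment(
        segs[0].seq[-params.k :] + random_seq(rng, 400), segs[0].right, None
    )
    n_before = len(registry)
    pl2 = registry.place(alien)[0]
    assert pl2.tokens is None and len(registry) == n_before + 1
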