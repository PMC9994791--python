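"""Archive container: round trips, determinism, append, block accounting."""

import hashlib

import pytest

from genarc import (
    ArchiveBuilder,
    ArchiveReader,
    DuplicateSampleError,
    append_archive,
    build_archive,
)
from genarc.format import read_footer
from genarc.model import Params
from genarc.sequence import ingest


def collection_of(path):
    with ArchiveReader(path) as reader:
        return [
            (g.name, [(n, s) for n, s in g.contigs]) for g in reader.get_collection()
        ]


def test_reference_only_round_trip(tmp_path, small_collection):
    ref, _, _ = small_collection
    path = tmp_path / "ref.gar"
    build_archive(path, ref, params=Params(k=17, segment_size=3000))
    with ArchiveReader(path) as reader:
        assert reader.list_samples() == [ref.name]
        genome = reader.get_sample(ref.name)
        assert [(n, ingest(s)) for n, s in ref.contigs] == genome.contigs


def test_full_collection_round_trip(small_archive, small_collection):
    ref, samples, _ = small_collection
    decoded = dict(collection_of(small_archive))
    for genome in [ref] + samples:
        assert [(n, ingest(s)) for n, s in genome.contigs] == decoded[genome.name]


def test_default_params_recorded_in_header(tmp_path, small_collection):
    ref, _, _ = small_collection
    path = tmp_path / "defaults.gar"
    build_archive(path, ref)
    with ArchiveReader(path) as reader:
        assert reader.params.k == 31
        assert reader.params.segment_size == 60000
        assert reader.params.block_size == 50
        assert reader.params.adaptive is False


def test_create_is_deterministic(tmp_path, small_collection, small_params):
    ref, samples, _ = small_collection
    digests = []
    for name in ("a.gar", "b.gar"):
        path = tmp_path / name
        build_archive(path, ref, samples, small_params)
        digests.append(hashlib.sha256(path.read_bytes()).hexdigest())
    assert digests[0] == digests[1]


def test_duplicate_sample_rejected(tmp_path, small_collection, small_params):
    ref, samples, _ = small_collection
    path = tmp_path / "dup.gar"
    builder = ArchiveBuilder.create(path, ref, small_params)
    with pytest.raises(DuplicateSampleError, match=ref.name):
        builder.add_genome(ref)


def test_append_equivalence_and_immutability(tmp_path, small_collection, small_params):
    ref, samples, _ = small_collection
    batch = tmp_path / "batch.gar"
    build_archive(batch, ref, samples, small_params)
    grown = tmp_path / "grown.gar"
    build_archive(grown, ref, samples[:2], small_params)
    pre = grown.read_bytes()
    with open(grown, "rb") as fh:
        pre_meta_off, _ = read_footer(fh)
    append_archive(grown, samples[2:])
    post = grown.read_bytes()
    # identical decompressed collections
    assert collection_of(batch) == collection_of(grown)
    # the pre-append data region (every previously written frame) is intact
    assert post[:pre_meta_off] == pre[:pre_meta_off]


def test_reseal_without_new_samples_preserves_content(
    tmp_path, small_collection, small_params
):
    ref, samples, _ = small_collection
    path = tmp_path / "reseal.gar"
    build_archive(path, ref, samples, small_params)
    before = collection_of(path)
    builder = ArchiveBuilder.open_for_append(path)
    builder.seal_and_write()
    assert collection_of(path) == before


def test_block_size_one_never_larger_than_fifty(tmp_path, small_collection):
    ref, samples, _ = small_collection
    sizes = {}
    for b in (1, 5):
        path = tmp_path / f"b{b}.gar"
        build_archive(path, ref, samples, Params(k=17, segment_size=3000, block_size=b))
        sizes[b] = path.stat().st_size
    assert sizes[1] >= sizes[5]


def test_block_counts_respect_block_size(small_archive, small_params):
    with ArchiveReader(small_archive) as reader:
        for g in reader.meta.groups:
            for block in g.blocks[:-1]:
                assert block.count == small_params.block_size
            if g.blocks:
                assert 1 <= g.blocks[-1].count <= small_params.block_size


def test_toc_offsets_within_file(small_archive):
    size = small_archive.stat().st_size
    with ArchiveReader(small_archive) as reader:
        for g in reader.meta.groups:
            assert 8 <= g.ref_offset and g.ref_offset + g.ref_csize <= size
            for b in g.blocks:
                assert 8 <= b.offset and b.offset + b.csize <= size


def test_identical_genome_adds_little(tmp_path, small_collection, small_params):
    ref, _, _ = small_collection
    solo = tmp_path / "solo.gar"
    build_archive(solo, ref, params=small_params)
    twice = tmp_path / "twice.gar"
    twin = type(ref)("twin", list(ref.contigs))
    build_archive(twice, ref, [twin], small_params)
    growth = twice.stat().st_size - solo.stat().st_size
    # far below the ~2-bit/base packed size of the duplicate genome
    assert growth < 0.05 * (ref.total_length() / 4)


def test_foreign_contig_stored_in_bucket_group(tmp_path, small_collection, small_params):
    import numpy as np

    from tests.conftest import random_seq

    ref, _, _ = small_collection
    rng = np.random.default_rng(99)
    alien = type(ref)("alien", [("novel", random_seq(rng, 5000))])
    path = tmp_path / "alien.gar"
    build_archive(path, ref, [alien], small_params)
    with ArchiveReader(path) as reader:
        assert reader.info()["spt0_segments"] >= 1
        assert reader.get_contig("alien", "novel") == alien.contigs[0][1]
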