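"""LZSS codec: parse/decode identity, costs, division points."""

import numpy as np
import pytest

from genarc.lzss import (
    LIT,
    MATCH,
    CorruptStreamError,
    ReferenceIndex,
    cost,
    deserialize,
    find_division_point,
    lzss_decode,
    lzss_parse,
    parse_cost,
    prefix_costs,
    serialize,
    suffix_costs,
)
from tests.conftest import random_seq

MM = 20  # min_match
M = 16   # match-finder m-mer length


def index(ref: bytes) -> ReferenceIndex:
    return ReferenceIndex(ref, M)


def test_self_parse_is_single_match():
    rng = np.random.default_rng(1)
    ref = random_seq(rng, 500)
    tokens = lzss_parse(ref, index(ref), MM)
    assert tokens == [(MATCH, 0, len(ref))]


def test_unrelated_parse_is_all_literals():
    rng = np.random.default_rng(2)
    ref = random_seq(rng, 300)
    seq = random_seq(rng, 300)
    tokens = lzss_parse(seq, index(ref), MM)
    # random 300-mers share no 16-mer with overwhelming probability
    assert all(t[0] == LIT for t in tokens)
    assert lzss_decode(tokens, ref) == seq


def test_single_substitution_parse_shape():
    rng = np.random.default_rng(3)
    ref = random_seq(rng, 400)
    p = 200
    sub = b"A" if ref[p : p + 1] != b"A" else b"C"
    seq = ref[:p] + sub + ref[p + 1 :]
    tokens = lzss_parse(seq, index(ref), MM)
    assert tokens == [
        (MATCH, 0, p),
        (LIT, sub),
        (MATCH, p + 1, len(ref) - p - 1),
    ]


def test_decode_examples_and_errors():
    ref = b"ACGT" * 30
    assert lzss_decode([(MATCH, 0, len(ref))], ref) == ref
    assert lzss_decode([], ref) == b""
    with pytest.raises(CorruptStreamError):
        lzss_decode([(MATCH, 100, 50)], ref)


def test_round_trip_randomized_pairs():
    rng = np.random.default_rng(7)
    for _ in range(1500):
        ref = random_seq(rng, int(rng.integers(0, 800)))
        # mix of related and unrelated sequences
        if rng.random() < 0.5:
            seq = random_seq(rng, int(rng.integers(0, 800)))
        else:
            cut = int(rng.integers(0, max(len(ref), 1)))
            seq = ref[cut:] + random_seq(rng, int(rng.integers(0, 50)))
        idx = index(ref)
        tokens = lzss_parse(seq, idx, MM)
        assert lzss_decode(tokens, ref) == seq
        stream = serialize(tokens, MM)
        assert deserialize(stream, MM) == tokens
        assert len(stream) == cost(tokens, MM)


def test_parse_deterministic_serialization():
    rng = np.random.default_rng(9)
    ref = random_seq(rng, 600)
    seq = ref[50:550] + random_seq(rng, 30)
    a = serialize(lzss_parse(seq, index(ref), MM), MM)
    b = serialize(lzss_parse(seq, index(ref), MM), MM)
    assert a == b


def test_cost_properties():
    rng = np.random.default_rng(11)
    assert cost([], MM) == 1  # terminator only
    seq = random_seq(rng, 300)
    literal_only = cost([(LIT, seq)], MM)
    assert literal_only >= len(seq)
    # greedy cost never exceeds literal-only cost
    for _ in range(50):
        ref = random_seq(rng, 400)
        s = ref[: int(rng.integers(0, 400))] + random_seq(rng, int(rng.integers(0, 200)))
        assert parse_cost(s, index(ref), MM) <= cost([(LIT, s)], MM)
    # parsing against itself is cheaper than against unrelated material
    for _ in range(20):
        s = random_seq(rng, 250)
        unrelated = random_seq(rng, 250)
        assert parse_cost(s, index(s), MM) < parse_cost(s, index(unrelated), MM)
    # appending a token never decreases cost
    tokens = [(MATCH, 0, 30)]
    assert cost(tokens + [(LIT, b"A")], MM) > cost(tokens, MM)


def _exhaustive_division(seg, ref_a, ref_b):
    ia, ib = index(ref_a), index(ref_b)
    totals = [
        cost(lzss_parse(seg[:i], ia, MM), MM) + cost(lzss_parse(seg[i:], ib, MM), MM)
        for i in range(len(seg) + 1)
    ]
    return int(np.argmin(totals)), totals


def test_division_point_at_junction_of_concatenation():
    rng = np.random.default_rng(13)
    ref_a = random_seq(rng, 150)
    ref_b = random_seq(rng, 150)
    seg = ref_a + ref_b
    got = find_division_point(seg, ref_a, ref_b, MM, M)
    exp, _ = _exhaustive_division(seg, ref_a, ref_b)
    assert got == exp == len(ref_a)


def test_division_point_all_in_one_side():
    rng = np.random.default_rng(14)
    ref_b = random_seq(rng, 180)
    ref_a = random_seq(rng, 180)
    seg = ref_b  # shares nothing with ref_a, everything with ref_b
    assert find_division_point(seg, ref_a, ref_b, MM, M) == 0


def test_division_point_tie_breaks_to_smallest_index():
    rng = np.random.default_rng(15)
    seg = random_seq(rng, 50)  # unrelated to both references
    ref = random_seq(rng, 60)
    got = find_division_point(seg, ref, ref, MM, M)
    exp, totals = _exhaustive_division(seg, ref, ref)
    assert got == exp
    assert totals[got] == min(totals)


def test_prefix_and_suffix_costs_equal_exhaustive_parses():
    rng = np.random.default_rng(17)
    for trial in range(60):
        ref = random_seq(rng, int(rng.integers(20, 150)))
        if trial % 2:
            seg = ref[int(rng.integers(0, len(ref))) :] + random_seq(
                rng, int(rng.integers(0, 80))
            )
        else:
            seg = random_seq(rng, int(rng.integers(2, 150)))
        idx = index(ref)
        P = prefix_costs(seg, idx, MM)
        C = suffix_costs(seg, idx, MM)
        for i in range(len(seg) + 1):
            assert P[i] == cost(lzss_parse(seg[:i], idx, MM), MM)
            assert C[i] == cost(lzss_parse(seg[i:], idx, MM), MM)
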