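"""Kssd: dictionary construction, map/full equivalence, exact Jaccard."""

import numpy as np
import pytest

from genosketch import fixtures, sketchio
from genosketch.kssd import (
    KssdSketch,
    build_dictionary,
    build_map_dictionary,
    central_substring_codes,
    kssd_jaccard,
    kssd_sketch_records,
)
from genosketch.minhash import sketch_records  # noqa: F401  (family contrast in docs)
from genosketch.seqio import KmerConfig, extract_kmers


def test_dictionary_is_permutation_with_exact_valid_count():
    d = build_dictionary(half_k=3, drlevel=1, seed=42)
    assert sorted(d.perm) == list(range(64))
    assert int((d.perm < d.n_valid).sum()) == 16
    d0 = build_dictionary(half_k=3, drlevel=0, seed=42)
    assert int((d0.perm < d0.n_valid).sum()) == 64


def test_dictionary_deterministic_per_seed():
    a = build_dictionary(6, 3, seed=5)
    b = build_dictionary(6, 3, seed=5)
    c = build_dictionary(6, 3, seed=6)
    assert np.array_equal(a.perm, b.perm)
    assert a.dict_id == b.dict_id
    assert not np.array_equal(a.perm, c.perm)
    assert a.dict_id != c.dict_id


def test_dictionary_parameter_validation():
    with pytest.raises(ValueError, match="cannot reduce"):
        build_dictionary(half_k=3, drlevel=4)
    with pytest.raises(ValueError):
        build_dictionary(half_k=0, drlevel=0)


def test_map_dictionary_agrees_with_full_array_exhaustively():
    """Every code of the 4^L space: map lookup equals the permutation
    array for valid codes and reports absence otherwise."""
    d = build_dictionary(half_k=4, drlevel=2, seed=11)
    md = build_map_dictionary(d)
    assert len(md.mapping) == 16
    for code in range(d.space):
        rank = md.rank(code)
        if d.perm[code] < d.n_valid:
            assert rank == d.perm[code]
        else:
            assert rank is None


def test_map_dictionary_size_without_reduction():
    d = build_dictionary(half_k=3, drlevel=0, seed=1)
    assert len(build_map_dictionary(d).mapping) == d.space


def test_sketching_through_map_is_bit_identical():
    d = build_dictionary(half_k=6, drlevel=2, seed=42)
    md = build_map_dictionary(d)
    g = fixtures.random_genome(20000, 8)
    assert kssd_sketch_records([g], 21, d) == kssd_sketch_records([g], 21, md)


def test_drlevel_zero_keeps_every_distinct_kmer():
    d = build_dictionary(half_k=4, drlevel=0, seed=3)
    g = fixtures.random_genome(2000, 4)
    sk = kssd_sketch_records([g], 15, d)
    assert np.array_equal(sk.codes, fixtures.canonical_kmer_set(g, 15))


def test_selected_fraction_within_binomial_bound():
    d = build_dictionary(half_k=6, drlevel=2, seed=42)
    g = fixtures.random_genome(100000, 21)
    total = len(fixtures.canonical_kmer_set(g, 21))
    frac = len(kssd_sketch_records([g], 21, d).codes) / total
    p = 4.0 ** -2
    sd = np.sqrt(p * (1 - p) / total)
    assert abs(frac - p) <= 3 * sd


def test_jaccard_equals_brute_force_on_selected_sets():
    d = build_dictionary(half_k=6, drlevel=2, seed=42)
    a, b = fixtures.block_sharing_pair(20000, 10000, 3)
    ska = kssd_sketch_records([a], 21, d, name="a")
    skb = kssd_sketch_records([b], 21, d, name="b")
    # brute-force oracle: apply the dictionary to the full k-mer sets
    sel = {}
    for name, rec in (("a", a), ("b", b)):
        kmers = fixtures.canonical_kmer_set(rec, 21)
        sub = central_substring_codes(kmers, 21, 6)
        sel[name] = set(map(int, kmers[d.perm[sub] < d.n_valid]))
    expected = len(sel["a"] & sel["b"]) / len(sel["a"] | sel["b"])
    r = kssd_jaccard(ska, skb)
    assert r.jaccard == pytest.approx(expected, abs=1e-15)
    assert r.shared == len(sel["a"] & sel["b"])
    assert kssd_jaccard(ska, ska).jaccard == 1.0


def test_sketches_from_different_dictionaries_incomparable():
    d1 = build_dictionary(6, 2, seed=1)
    d2 = build_dictionary(6, 2, seed=2)
    g = fixtures.random_genome(1000, 5)
    with pytest.raises(ValueError, match="different dictionaries"):
        kssd_jaccard(kssd_sketch_records([g], 21, d1), kssd_sketch_records([g], 21, d2))


def test_k_smaller_than_substring_rejected():
    d = build_dictionary(6, 2, seed=1)
    g = fixtures.random_genome(100, 5)
    with pytest.raises(ValueError, match="smaller than"):
        KssdSketch(k=4, dict_id=d.dict_id).update(g, d)


def test_streaming_and_order_independent():
    d = build_dictionary(6, 3, seed=42)
    parts = [fixtures.random_genome(5000, 30 + i) for i in range(4)]
    fwd = kssd_sketch_records(parts, 21, d)
    rev = kssd_sketch_records(parts[::-1], 21, d)
    assert fwd == rev


def test_dictionary_and_sketch_serialization_roundtrip(tmp_path):
    d = build_dictionary(5, 2, seed=9)
    dpath = tmp_path / "dict.json"
    d.save(dpath)
    d2 = type(d).load(dpath)
    assert np.array_equal(d.perm, d2.perm) and d.dict_id == d2.dict_id
    g = fixtures.random_genome(3000, 10)
    sk = kssd_sketch_records([g], 17, d, name="g")
    spath = tmp_path / "k.gsk"
    sketchio.save_sketches([sk], spath)
    (back,) = sketchio.load_sketches(spath)
    assert back == sk
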