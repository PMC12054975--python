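"""KMV MinHash: bottom-s semantics, Mash estimator, merge algebra."""

import numpy as np
import pytest

from genosketch import fixtures, minhash, sketchio
from genosketch.minhash import MinHashSketch, hash_kmer_codes, jaccard, merge, sketch_records
from genosketch.seqio import SequenceRecord


def _brute_force_hashes(rec, k, seed=42):
    codes = fixtures.canonical_kmer_set(rec, k)
    return np.sort(hash_kmer_codes(codes, k, seed))


def test_sketch_is_bottom_s_of_full_hash_set():
    g = fixtures.random_genome(5000, 2)
    sk = sketch_records([g], k=21, s=1000)
    assert np.array_equal(sk.hashes, _brute_force_hashes(g, 21)[:1000])
    assert np.all(sk.hashes[:-1] < sk.hashes[1:])


def test_update_with_short_sequence_is_noop():
    sk = MinHashSketch(k=21, s=100)
    sk.update(SequenceRecord("x", "ACGT"))
    assert len(sk.hashes) == 0 and sk.n_kmers == 0


def test_update_is_idempotent_on_same_sequence():
    g = fixtures.random_genome(300, 5)
    a = MinHashSketch(k=11, s=500).update(g)
    b = MinHashSketch(k=11, s=500).update(g).update(g)
    assert a == b


def test_streaming_update_equals_batch_build():
    parts = [fixtures.random_genome(700, s, name=f"p{s}") for s in range(6)]
    streamed = MinHashSketch(k=15, s=300)
    for p in parts:
        streamed.update(p)
    batch = sketch_records(parts, k=15, s=300)
    # and order independence
    shuffled = sketch_records(parts[::-1], k=15, s=300)
    assert streamed == batch == shuffled


def test_update_k_mismatch_rejected():
    sk = MinHashSketch(k=21, s=10)
    with pytest.raises(ValueError, match="k-mer length mismatch"):
        sk.update(SequenceRecord("x", "ACGT" * 10), k=15)


def test_jaccard_self_is_one_and_disjoint_is_zero():
    g = fixtures.random_genome(2000, 9)
    a = sketch_records([g], k=21, s=100)
    assert jaccard(a, a).jaccard == 1.0
    assert jaccard(a, a).mash_distance == 0.0
    x = MinHashSketch(k=21, s=4, hashes=np.array([1, 2, 3, 4], np.uint64))
    y = MinHashSketch(k=21, s=4, hashes=np.array([5, 6, 7, 8], np.uint64))
    r = jaccard(x, y)
    assert r.jaccard == 0.0 and r.mash_distance == 1.0


def test_jaccard_equals_exact_when_sketch_holds_everything():
    a, b = fixtures.block_sharing_pair(5000, 2500, 7)
    ska = sketch_records([a], k=21, s=20000)
    skb = sketch_records([b], k=21, s=20000)
    r = jaccard(ska, skb)
    assert r.jaccard == pytest.approx(fixtures.exact_jaccard(a, b, 21), abs=1e-12)
    assert r.jaccard == r.shared / r.denom


def test_jaccard_incompatible_parameters_named_in_error():
    a = MinHashSketch(k=21, s=10)
    b = MinHashSketch(k=15, s=10)
    with pytest.raises(ValueError, match="21 vs 15"):
        jaccard(a, b)
    c = MinHashSketch(k=21, s=10, seed=7)
    with pytest.raises(ValueError, match="42 vs 7"):
        jaccard(a, c)


def test_merge_identity_idempotence_and_two_halves():
    g = fixtures.random_genome(4000, 13)
    half1 = SequenceRecord("h1", g.seq[:2010])
    half2 = SequenceRecord("h2", g.seq[1990:])  # overlap keeps boundary k-mers
    whole = sketch_records([g], k=21, s=500)
    m = merge(sketch_records([half1], 21, 500), sketch_records([half2], 21, 500))
    assert m == whole
    empty = MinHashSketch(k=21, s=500)
    assert merge(whole, empty) == whole
    assert merge(whole, whole) == whole
    with pytest.raises(ValueError):
        merge(whole, MinHashSketch(k=21, s=400))


def test_merge_commutative_associative():
    gs = [fixtures.random_genome(900, 20 + i) for i in range(3)]
    a, b, c = (sketch_records([g], 13, 200) for g in gs)
    assert merge(a, b) == merge(b, a)
    assert merge(merge(a, b), c) == merge(a, merge(b, c))


def test_estimator_consistency_small_scale(rng):
    """KMV estimate vs brute-force exact Jaccard over mutated genome pairs."""
    errors = []
    for i in range(30):
        base = fixtures.random_genome(20000, 500 + i)
        mut = fixtures.mutate(base, fixtures.MutationModel(0.02, 900 + i))
        j_exact = fixtures.exact_jaccard(base, mut, 21)
        est = jaccard(sketch_records([base], 21, 1000), sketch_records([mut], 21, 1000))
        errors.append(est.jaccard - j_exact)
        bound = 4 * np.sqrt(j_exact * (1 - j_exact) / 1000)
        assert abs(errors[-1]) <= bound
    assert abs(np.mean(errors)) <= 0.01


def test_serialization_roundtrip_bit_exact(tmp_path):
    g = fixtures.random_genome(3000, 77)
    sk = sketch_records([g], k=21, s=250, name="g77")
    path = tmp_path / "s.gsk"
    sketchio.save_sketches([sk], path)
    (back,) = sketchio.load_sketches(path)
    assert back == sk and back.name == "g77" and back.n_kmers == sk.n_kmers
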