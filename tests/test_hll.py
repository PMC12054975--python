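"""HyperLogLog: register semantics, estimator calibration, merge lattice."""

import numpy as np
import pytest

from genosketch import fixtures, sketchio
from genosketch.hll import HLLSketch, hll_jaccard, hll_merge, hll_sketch_records


def _scalar_reference_add(registers, p, value):
    """Branchy scalar reference for register updates, independent of the
    vectorized path."""
    bucket = value >> (64 - p)
    suffix = (value << p) & 0xFFFFFFFFFFFFFFFF
    if suffix == 0:
        rank = 64 - p + 1
    else:
        lz = 0
        probe = 1 << 63
        while not suffix & probe:
            lz += 1
            probe >>= 1
        rank = lz + 1
    if rank > registers[bucket]:
        registers[bucket] = rank


def _scalar_reference_cardinality(registers, p):
    """Branchy scalar reference for the bias-corrected estimator."""
    m = 1 << p
    if m == 16:
        alpha = 0.673
    elif m == 32:
        alpha = 0.697
    elif m == 64:
        alpha = 0.709
    else:
        alpha = 0.7213 / (1 + 1.079 / m)
    raw = alpha * m * m / sum(2.0 ** -int(r) for r in registers)
    zeros = sum(1 for r in registers if r == 0)
    if raw <= 2.5 * m and zeros:
        return m * np.log(m / zeros)
    return raw


def test_fresh_sketch_all_zero_and_estimate_zero():
    sk = HLLSketch(p=10)
    assert not sk.registers.any()
    assert sk.cardinality() == 0.0


def test_single_insertion_sets_exactly_one_register():
    sk = HLLSketch(p=10).add_hash(123456789)
    assert int((sk.registers > 0).sum()) == 1


def test_insertion_idempotent_and_monotone(rng):
    sk = HLLSketch(p=8)
    vals = rng.integers(0, 2**64, 100, dtype=np.uint64)
    sk.add_hashes(vals)
    before = sk.registers.copy()
    sk.add_hashes(vals)
    assert np.array_equal(sk.registers, before)
    sk.add_hashes(rng.integers(0, 2**64, 100, dtype=np.uint64))
    assert np.all(sk.registers >= before)


def test_register_values_within_rank_range(rng):
    p = 6
    sk = HLLSketch(p=p)
    sk.add_hashes(rng.integers(0, 2**64, 5000, dtype=np.uint64))
    sk.add_hash(0)  # all-zero suffix hits the maximal rank
    assert sk.registers.max() <= 64 - p + 1


def test_vectorized_add_matches_scalar_reference(rng):
    p = 8
    sk = HLLSketch(p=p)
    vals = rng.integers(0, 2**64, 2000, dtype=np.uint64)
    vals[:3] = [0, 1, 1 << 63]  # degenerate suffixes
    sk.add_hashes(vals)
    ref = [0] * (1 << p)
    for v in vals:
        _scalar_reference_add(ref, p, int(v))
    assert list(sk.registers) == ref


def test_cardinality_matches_scalar_reference(rng):
    for n in (10, 1000, 20000):
        sk = HLLSketch(p=10)
        sk.add_hashes(rng.integers(0, 2**64, n, dtype=np.uint64))
        assert sk.cardinality() == pytest.approx(
            _scalar_reference_cardinality(list(sk.registers), 10), rel=1e-12
        )


def test_cardinality_10k_within_5_percent():
    errs = []
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        sk = HLLSketch(p=14)
        sk.add_hashes(rng.integers(0, 2**64, 10000, dtype=np.uint64))
        err = abs(sk.cardinality() - 10000) / 10000
        errs.append(err)
        assert err <= 0.05
    assert np.mean(errs) <= 0.02


def test_merge_lattice_properties(rng):
    a = HLLSketch(p=8)
    b = HLLSketch(p=8)
    a.add_hashes(rng.integers(0, 2**64, 500, dtype=np.uint64))
    b.add_hashes(rng.integers(0, 2**64, 500, dtype=np.uint64))
    empty = HLLSketch(p=8)
    assert hll_merge(a, empty) == a
    assert hll_merge(a, a) == a
    assert hll_merge(a, b) == hll_merge(b, a)
    with pytest.raises(ValueError):
        hll_merge(a, HLLSketch(p=9))


def test_merge_of_disjoint_streams_equals_union_stream(rng):
    x = rng.integers(0, 2**63, 3000, dtype=np.uint64)
    y = rng.integers(2**63, 2**64, 3000, dtype=np.uint64)
    a = HLLSketch(p=12).add_hashes(x)
    b = HLLSketch(p=12).add_hashes(y)
    u = HLLSketch(p=12).add_hashes(np.concatenate([x, y]))
    assert hll_merge(a, b) == u


def test_update_from_sequences_estimates_kmer_count():
    g = fixtures.random_genome(12000, 44)
    sk = hll_sketch_records([g], k=21, p=14)
    exact = len(fixtures.canonical_kmer_set(g, 21))
    assert abs(sk.cardinality() - exact) / exact <= 0.05


def test_jaccard_self_high_disjoint_low(rng):
    vals = rng.integers(0, 2**64, 10000, dtype=np.uint64)
    a = HLLSketch(p=14).add_hashes(vals)
    assert hll_jaccard(a, a).jaccard >= 0.95
    b = HLLSketch(p=14).add_hashes(rng.integers(0, 2**64, 10000, dtype=np.uint64))
    r = hll_jaccard(a, b)
    assert r.jaccard <= 0.05
    assert 0.0 <= r.jaccard <= 1.0


def test_serialization_roundtrip(tmp_path):
    g = fixtures.random_genome(2000, 55)
    sk = hll_sketch_records([g], k=21, p=10, name="g55")
    path = tmp_path / "h.gsk"
    sketchio.save_sketches([sk], path)
    (back,) = sketchio.load_sketches(path)
    assert back == sk and back.cardinality() == sk.cardinality()
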