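"""HyperLogLog cardinality sketching over k-mer hash streams.

Each 64-bit hash is routed to one of 2^p registers by its top p bits; the
register keeps the maximum "rank" seen, where rank = number of leading
zeros of the remaining 64-p bits plus one.  Cardinality is recovered with
the bias-corrected harmonic-mean estimator of the original HyperLogLog,
switching to linear counting in the small range (raw estimate below
2.5·2^p with empty registers present).  With 64-bit hashes no large-range
correction is needed.

Merging is register-wise max — an exact join, so merge(sketch(X),
sketch(Y)) equals sketch(X ∪ Y) register for register.  Jaccard between
two sketches uses inclusion–exclusion on the three cardinalities.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass, field

import numpy as np

from . import distcore, seqio
from .distcore import DistanceResult
from .hashing import DEFAULT_SEED
from .minhash import hash_kmer_codes

__all__ = ["HLLSketch", "hll_sketch_records", "hll_merge", "hll_jaccard"]

DEFAULT_P = 14


def _alpha(m: int) -> float:
    if m == 16:
        return 0.673
    if m == 32:
        return 0.697
    if m == 64:
        return 0.709
    return 0.7213 / (1.0 + 1.079 / m)


@dataclass
class HLLSketch:
    """2^p registers of maximal leading-zero ranks."""

    p: int = DEFAULT_P
    k: int = 21
    seed: int = DEFAULT_SEED
    name: str = ""
    registers: np.ndarray = field(default=None)  # uint8, length 2^p

    def __post_init__(self) -> None:
        if not (4 <= self.p <= 18):
            raise ValueError(f"precision p must be in [4, 18], got {self.p}")
        if self.registers is None:
            self.registers = np.zeros(1 << self.p, dtype=np.uint8)
        else:
            self.registers = np.asarray(self.registers, dtype=np.uint8)
            if len(self.registers) != (1 << self.p):
                raise ValueError("register array length must be 2^p")

    def copy(self) -> "HLLSketch":
        return HLLSketch(self.p, self.k, self.seed, self.name, self.registers.copy())

    def add_hash(self, value: int) -> "HLLSketch":
        self.add_hashes(np.array([value], dtype=np.uint64))
        return self

    def add_hashes(self, values: np.ndarray) -> "HLLSketch":
        """Fold 64-bit hash values into the registers (vectorized)."""
        values = np.asarray(values, dtype=np.uint64)
        if len(values) == 0:
            return self
        p = np.uint64(self.p)
        buckets = (values >> (np.uint64(64) - p)).astype(np.intp)
        suffix = values << p  # remaining 64-p bits, left-aligned
        ranks = _leading_zeros64(suffix)
        ranks = np.minimum(ranks, 64 - self.p).astype(np.uint8) + np.uint8(1)
        np.maximum.at(self.registers, buckets, ranks)
        return self

    def update(self, rec: seqio.SequenceRecord) -> "HLLSketch":
        """Fold all canonical k-mers of one sequence into the sketch."""
        stream = seqio.extract_kmers(rec, seqio.KmerConfig(k=self.k, canonical=True))
        if len(stream) == 0:
            return self
        codes = np.unique(stream.codes)
        self.add_hashes(hash_kmer_codes(codes, self.k, self.seed))
        return self

    def cardinality(self) -> float:
        """Bias-corrected HLL estimate with small-range linear counting."""
        m = 1 << self.p
        reg = self.registers.astype(np.float64)
        raw = _alpha(m) * m * m / np.sum(np.exp2(-reg))
        zeros = int(np.count_nonzero(self.registers == 0))
        if raw <= 2.5 * m and zeros > 0:
            return float(m * np.log(m / zeros))
        return float(raw)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HLLSketch):
            return NotImplemented
        return (self.p == other.p and self.k == other.k and self.seed == other.seed
                and np.array_equal(self.registers, other.registers))

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "algorithm": "hll",
            "p": self.p,
            "k": self.k,
            "seed": self.seed,
            "name": self.name,
            "registers": base64.b64encode(self.registers.tobytes()).decode("ascii"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HLLSketch":
        regs = np.frombuffer(base64.b64decode(d["registers"]), dtype=np.uint8).copy()
        return cls(p=int(d["p"]), k=int(d["k"]), seed=int(d["seed"]),
                   name=d.get("name", ""), registers=regs)


def _leading_zeros64(x: np.ndarray) -> np.ndarray:
    """Leading-zero count of each uint64 (64 for zero)."""
    x = np.asarray(x, dtype=np.uint64)
    nz = x != 0
    # bit length via float64 exponent is unsafe above 2^53; use a halving cascade
    out = np.full(len(x), 64, dtype=np.int64)
    v = x.copy()
    shift = np.zeros(len(x), dtype=np.uint64)
    for s in (32, 16, 8, 4, 2, 1):
        mask = v >= (np.uint64(1) << np.uint64(s))
        v[mask] >>= np.uint64(s)
        shift[mask] += np.uint64(s)
    out[nz] = 63 - shift[nz].astype(np.int64)
    return out


def hll_sketch_records(records: list[seqio.SequenceRecord], k: int,
                       p: int = DEFAULT_P, seed: int = DEFAULT_SEED,
                       name: str = "") -> HLLSketch:
    sk = HLLSketch(p=p, k=k, seed=seed, name=name)
    for rec in records:
        sk.update(rec)
    return sk


def _check_compatible(a: HLLSketch, b: HLLSketch) -> None:
    if a.p != b.p:
        raise ValueError(f"incompatible precision: {a.p} vs {b.p}")
    if a.seed != b.seed:
        raise ValueError(f"incompatible seed: {a.seed} vs {b.seed}")
    if a.k != b.k:
        raise ValueError(f"incompatible k: {a.k} vs {b.k}")


def hll_merge(a: HLLSketch, b: HLLSketch) -> HLLSketch:
    """Register-wise max: commutative, associative, idempotent."""
    _check_compatible(a, b)
    out = a.copy()
    out.name = a.name or b.name
    np.maximum(out.registers, b.registers, out=out.registers)
    return out


def hll_jaccard(a: HLLSketch, b: HLLSketch) -> DistanceResult:
    """Inclusion–exclusion Jaccard estimate, clamped to [0, 1]."""
    _check_compatible(a, b)
    ca = a.cardinality()
    cb = b.cardinality()
    cu = hll_merge(a, b).cardinality()
    if cu <= 0:
        return DistanceResult(jaccard=0.0, mash_distance=1.0, shared=0.0, denom=0.0)
    inter = max(0.0, ca + cb - cu)
    j = min(1.0, inter / cu)
    return DistanceResult(jaccard=j, mash_distance=distcore.mash_distance(j, a.k),
                          shared=inter, denom=cu)
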