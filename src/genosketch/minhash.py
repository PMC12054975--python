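"""KMV (bottom-s) MinHash sketching and Mash-style distance estimation.

A sketch retains the s smallest distinct MurmurHash3 values over the
canonical k-mers of one or more sequences.  Because the retained set is
the bottom-s of everything seen so far, streaming updates, batch builds
and merges all yield bit-identical sketches.

The Jaccard estimate follows the Mash convention: merge the two sorted
hash lists, keep the s' = min(s, |union|) smallest values of the union,
and count how many of those occur in both sketches; j = shared / s'.
The Mash distance is D = -(1/k)·ln(2j/(1+j)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import distcore, hashing, seqio
from .distcore import DistanceResult
from .hashing import DEFAULT_SEED

__all__ = ["MinHashSketch", "sketch_records", "jaccard", "merge", "mash_distance"]

mash_distance = distcore.mash_distance


def hash_kmer_codes(codes: np.ndarray, k: int, seed: int) -> np.ndarray:
    """MurmurHash3-64 of packed k-mer codes via their ASCII serialization."""
    ascii_mat = seqio.codes_to_ascii(codes, k)
    return hashing.murmur64_fixed_batch(ascii_mat, seed)


@dataclass
class MinHashSketch:
    """Bottom-s sketch of a k-mer hash set.

    ``hashes`` is strictly increasing with at most ``s`` entries; once the
    sketch is full, every retained value is no larger than any value ever
    discarded.  ``n_kmers`` counts k-mer windows consumed (not distinct).
    """

    k: int
    s: int
    seed: int = DEFAULT_SEED
    name: str = ""
    hashes: np.ndarray = field(default_factory=lambda: np.empty(0, np.uint64))
    n_kmers: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.k > 32:
            raise ValueError(f"k must be in [1, 32], got {self.k}")
        if self.s < 1:
            raise ValueError(f"sketch size s must be >= 1, got {self.s}")
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)

    def copy(self) -> "MinHashSketch":
        return MinHashSketch(self.k, self.s, self.seed, self.name,
                             self.hashes.copy(), self.n_kmers)

    def _fold(self, new_hashes: np.ndarray) -> None:
        union = np.union1d(self.hashes, new_hashes)
        self.hashes = union[: self.s]

    def update(self, rec: seqio.SequenceRecord, k: int | None = None) -> "MinHashSketch":
        """Fold all canonical k-mers of one sequence into the sketch.

        Streaming contract: updating record by record equals one batch
        build over the concatenated k-mer multiset.
        """
        if k is not None and k != self.k:
            raise ValueError(f"k-mer length mismatch: sketch has k={self.k}, caller passed k={k}")
        stream = seqio.extract_kmers(rec, seqio.KmerConfig(k=self.k, canonical=True))
        self.n_kmers += len(stream)
        if len(stream) == 0:
            return self
        codes = np.unique(stream.codes)
        self._fold(hash_kmer_codes(codes, self.k, self.seed))
        return self

    def update_hashes(self, values: np.ndarray) -> "MinHashSketch":
        """Fold raw 64-bit hash values directly (advanced use)."""
        self._fold(np.unique(np.asarray(values, dtype=np.uint64)))
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MinHashSketch):
            return NotImplemented
        return (
            self.k == other.k
            and self.s == other.s
            and self.seed == other.seed
            and np.array_equal(self.hashes, other.hashes)
        )

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "algorithm": "minhash",
            "k": self.k,
            "s": self.s,
            "seed": self.seed,
            "name": self.name,
            "n_kmers": self.n_kmers,
            "hashes": [str(int(h)) for h in self.hashes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinHashSketch":
        return cls(
            k=int(d["k"]), s=int(d["s"]), seed=int(d["seed"]),
            name=d.get("name", ""),
            hashes=np.array([int(x) for x in d["hashes"]], dtype=np.uint64),
            n_kmers=int(d.get("n_kmers", 0)),
        )


def sketch_records(
    records: list[seqio.SequenceRecord],
    k: int,
    s: int,
    seed: int = DEFAULT_SEED,
    name: str = "",
) -> MinHashSketch:
    """Build one sketch over all records (per-file sketching)."""
    sk = MinHashSketch(k=k, s=s, seed=seed, name=name)
    for rec in records:
        sk.update(rec)
    return sk


def _check_compatible(a: MinHashSketch, b: MinHashSketch, need_s: bool = False) -> None:
    if a.k != b.k:
        raise ValueError(f"incompatible k: {a.k} vs {b.k}")
    if a.seed != b.seed:
        raise ValueError(f"incompatible seed: {a.seed} vs {b.seed}")
    if need_s and a.s != b.s:
        raise ValueError(f"incompatible sketch size: {a.s} vs {b.s}")


def jaccard(a: MinHashSketch, b: MinHashSketch, method: str = "block") -> DistanceResult:
    """Mash-style Jaccard estimate between two sketches.

    The shared count is produced by a sorted-list merge (or the blocked
    equivalent); restricting the union to its s' smallest values keeps the
    estimator unbiased when sketches are full.
    """
    _check_compatible(a, b)
    s = min(a.s, b.s)
    union = np.union1d(a.hashes, b.hashes)
    denom = min(s, len(union))
    if denom == 0:
        return DistanceResult(jaccard=0.0, mash_distance=1.0, shared=0, denom=0)
    cutoff = union[denom - 1]
    a_low = a.hashes[: int(np.searchsorted(a.hashes, cutoff, side="right"))]
    b_low = b.hashes[: int(np.searchsorted(b.hashes, cutoff, side="right"))]
    shared = distcore.intersect_count(a_low, b_low, method=method)
    j = shared / denom
    return DistanceResult(
        jaccard=j,
        mash_distance=distcore.mash_distance(j, a.k),
        shared=shared,
        denom=denom,
    )


def merge(a: MinHashSketch, b: MinHashSketch) -> MinHashSketch:
    """Bottom-s of the union of two sketches; equals sketching X ∪ Y."""
    _check_compatible(a, b, need_s=True)
    out = a.copy()
    out.name = a.name or b.name
    out._fold(b.hashes)
    out.n_kmers = a.n_kmers + b.n_kmers
    return out
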