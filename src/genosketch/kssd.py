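"""Kssd sketching: k-mer substring space sampling.

A seeded Fisher–Yates shuffle of the 4^L codes of a central length-L
substring assigns every code a rank; the codes ranked below 4^(L-d) are
"valid" and select a deterministic 1/4^d fraction of all k-mers.  Because
selection depends only on the dictionary, sketches of different genomes
built from the same dictionary sample the same k-mer subspace and can be
intersected exactly — Jaccard is |A∩B| / |A∪B| over the selected sets.

The shuffle PRNG is pinned to numpy's PCG64 so dictionaries are
reproducible across runs and platforms; a digest of (L, d, seed, perm)
binds each sketch to its dictionary.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import distcore, seqio
from .distcore import DistanceResult

__all__ = [
    "KssdDictionary",
    "KssdMapDictionary",
    "KssdSketch",
    "build_dictionary",
    "build_map_dictionary",
    "kssd_sketch_records",
    "kssd_jaccard",
]

DEFAULT_HALF_K = 6
DEFAULT_DRLEVEL = 3


@dataclass
class KssdDictionary:
    """Shuffled substring code space.

    ``perm[c]`` is the shuffled rank of code ``c`` over [0, 4^half_k);
    code c is valid iff ``perm[c] < 4^(half_k - drlevel)``.
    """

    half_k: int
    drlevel: int
    seed: int
    perm: np.ndarray  # int64, a permutation of [0, 4^half_k)

    @property
    def space(self) -> int:
        return 4 ** self.half_k

    @property
    def n_valid(self) -> int:
        return 4 ** (self.half_k - self.drlevel)

    @property
    def dict_id(self) -> str:
        payload = json.dumps(
            [self.half_k, self.drlevel, self.seed,
             zlib.crc32(np.ascontiguousarray(self.perm, dtype="<i8").tobytes())]
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def is_valid_code(self, codes: np.ndarray) -> np.ndarray:
        return self.perm[np.asarray(codes, dtype=np.int64)] < self.n_valid

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "half_k": self.half_k,
            "drlevel": self.drlevel,
            "seed": self.seed,
            "perm": [int(x) for x in self.perm],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KssdDictionary":
        return cls(half_k=int(d["half_k"]), drlevel=int(d["drlevel"]),
                   seed=int(d["seed"]),
                   perm=np.array(d["perm"], dtype=np.int64))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "KssdDictionary":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_dictionary(half_k: int = DEFAULT_HALF_K, drlevel: int = DEFAULT_DRLEVEL,
                     seed: int = 42) -> KssdDictionary:
    """Seeded shuffle of the 4^half_k substring code space."""
    if not (1 <= half_k <= 10):
        raise ValueError(f"half_k must be in [1, 10], got {half_k}")
    if not (0 <= drlevel <= half_k):
        raise ValueError(
            f"drlevel must be in [0, half_k]; got drlevel={drlevel}, half_k={half_k} "
            "(cannot reduce below one code)"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    perm = rng.permutation(4 ** half_k).astype(np.int64)
    return KssdDictionary(half_k=half_k, drlevel=drlevel, seed=seed, perm=perm)


@dataclass
class KssdMapDictionary:
    """Compact map holding only the valid codes.

    Exactly 4^(half_k - drlevel) entries; lookups agree with the full
    permutation array on valid codes and report absence for the rest.
    Sketching through the map is bit-identical to sketching through the
    full array.
    """

    half_k: int
    drlevel: int
    seed: int
    dict_id: str
    mapping: dict[int, int]

    @property
    def n_valid(self) -> int:
        return 4 ** (self.half_k - self.drlevel)

    def rank(self, code: int) -> int | None:
        return self.mapping.get(int(code))

    def is_valid_code(self, codes: np.ndarray) -> np.ndarray:
        return np.fromiter(
            (int(c) in self.mapping for c in np.asarray(codes).ravel()),
            dtype=bool, count=len(np.asarray(codes).ravel()),
        )


def build_map_dictionary(dictionary: KssdDictionary) -> KssdMapDictionary:
    valid = np.nonzero(dictionary.perm < dictionary.n_valid)[0]
    mapping = {int(c): int(dictionary.perm[c]) for c in valid}
    return KssdMapDictionary(
        half_k=dictionary.half_k, drlevel=dictionary.drlevel,
        seed=dictionary.seed, dict_id=dictionary.dict_id, mapping=mapping,
    )


@dataclass
class KssdSketch:
    """Set of selected canonical k-mers, bound to one dictionary."""

    k: int
    dict_id: str
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, np.uint64))
    name: str = ""
    n_kmers: int = 0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)

    def update(self, rec: seqio.SequenceRecord,
               dictionary: KssdDictionary | KssdMapDictionary) -> "KssdSketch":
        """Add the dictionary-selected canonical k-mers of one record."""
        half_k = dictionary.half_k
        if self.k < half_k:
            raise ValueError(f"k={self.k} smaller than substring length {half_k}")
        if dictionary.dict_id != self.dict_id:
            raise ValueError("sketch is bound to a different dictionary")
        stream = seqio.extract_kmers(rec, seqio.KmerConfig(k=self.k, canonical=True))
        self.n_kmers += len(stream)
        if len(stream) == 0:
            return self
        kmers = np.unique(stream.codes)
        sub = central_substring_codes(kmers, self.k, half_k)
        selected = kmers[dictionary.is_valid_code(sub)]
        self.codes = np.union1d(self.codes, selected)
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KssdSketch):
            return NotImplemented
        return (self.k == other.k and self.dict_id == other.dict_id
                and np.array_equal(self.codes, other.codes))

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "algorithm": "kssd",
            "k": self.k,
            "dict_id": self.dict_id,
            "name": self.name,
            "n_kmers": self.n_kmers,
            "hashes": [str(int(c)) for c in self.codes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KssdSketch":
        return cls(k=int(d["k"]), dict_id=d["dict_id"], name=d.get("name", ""),
                   codes=np.array([int(x) for x in d["hashes"]], dtype=np.uint64),
                   n_kmers=int(d.get("n_kmers", 0)))


def central_substring_codes(kmer_codes: np.ndarray, k: int, half_k: int) -> np.ndarray:
    """Code of the central length-half_k substring of each packed k-mer.

    The substring starts at base (k - half_k) // 2, the Kssd centering
    convention; requires k >= half_k.
    """
    if k < half_k:
        raise ValueError(f"k={k} must be >= substring length {half_k}")
    start = (k - half_k) // 2
    shift = np.uint64(2 * (k - start - half_k))
    mask = np.uint64(4 ** half_k - 1)
    return ((np.asarray(kmer_codes, dtype=np.uint64) >> shift) & mask).astype(np.int64)


def kssd_sketch_records(
    records: list[seqio.SequenceRecord],
    k: int,
    dictionary: KssdDictionary | KssdMapDictionary,
    name: str = "",
) -> KssdSketch:
    sk = KssdSketch(k=k, dict_id=dictionary.dict_id, name=name)
    for rec in records:
        sk.update(rec, dictionary)
    return sk


def kssd_jaccard(a: KssdSketch, b: KssdSketch, method: str = "block") -> DistanceResult:
    """Exact Jaccard of the two selected-k-mer sets, plus Mash distance."""
    if a.dict_id != b.dict_id:
        raise ValueError(
            "sketches from different dictionaries are incomparable: "
            f"{a.dict_id} vs {b.dict_id}"
        )
    if a.k != b.k:
        raise ValueError(f"incompatible k: {a.k} vs {b.k}")
    shared = distcore.intersect_count(a.codes, b.codes, method=method)
    denom = len(a.codes) + len(b.codes) - shared
    if denom == 0:
        return DistanceResult(jaccard=0.0, mash_distance=1.0, shared=0, denom=0)
    j = shared / denom
    return DistanceResult(jaccard=j, mash_distance=distcore.mash_distance(j, a.k),
                          shared=shared, denom=denom)
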