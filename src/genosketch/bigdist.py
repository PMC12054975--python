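"""All-vs-all genome comparison via an inverted hash index.

For pure-hash sketches (KMV MinHash and Kssd, where the sketch is just a
sorted set of 64-bit values) the quadratic loop over sketch pairs can be
replaced by an inverted index mapping each hash value to the sketches
containing it.  Shared counts for every pair then accumulate in a single
sweep over the distinct hash values.  The index is an acceleration, not
an approximation: its results must equal the naive pairwise loop exactly,
and that equality is the module's core contract.

The MinHash estimator needs one extra ingredient: Mash's denominator is
the bottom-s' of the *union* of each pair's hash lists, so the sweep
visits hash values in ascending order and stops crediting shared hashes
to a pair once that pair's union counter reaches s (union-rank
streaming).  For Kssd the denominator is |A| + |B| − shared and no rank
bookkeeping is needed; the same sweep covers both by leaving every pair
active.

The compact index stores postings only for hash values observed in at
least one sketch — memory scales with distinct observed hashes, never
with the 64-bit hash space.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import kssd as kssd_mod
from . import minhash as minhash_mod
from .distcore import DistanceResult

__all__ = ["IndexDict", "PairwiseResult", "build_index", "all_vs_all", "pairwise_loop"]

PureHashSketch = minhash_mod.MinHashSketch | kssd_mod.KssdSketch


def _sketch_hashes(sk: PureHashSketch) -> np.ndarray:
    return sk.hashes if isinstance(sk, minhash_mod.MinHashSketch) else sk.codes


def _validate_family(sketches: Sequence[PureHashSketch]) -> str:
    if not sketches:
        raise ValueError("no sketches given")
    first = sketches[0]
    if isinstance(first, minhash_mod.MinHashSketch):
        algo = "minhash"
        for sk in sketches[1:]:
            if not isinstance(sk, minhash_mod.MinHashSketch):
                raise ValueError("mixed sketch algorithms in one index")
            if (sk.k, sk.s, sk.seed) != (first.k, first.s, first.seed):
                raise ValueError(
                    f"mixed minhash parameters: (k,s,seed)={(sk.k, sk.s, sk.seed)} "
                    f"vs {(first.k, first.s, first.seed)}"
                )
    elif isinstance(first, kssd_mod.KssdSketch):
        algo = "kssd"
        for sk in sketches[1:]:
            if not isinstance(sk, kssd_mod.KssdSketch):
                raise ValueError("mixed sketch algorithms in one index")
            if (sk.k, sk.dict_id) != (first.k, first.dict_id):
                raise ValueError(
                    f"mixed kssd parameters: (k,dict_id)={(sk.k, sk.dict_id)} "
                    f"vs {(first.k, first.dict_id)}"
                )
    else:
        raise ValueError(
            f"index engine requires pure-hash sketches, got {type(first).__name__}"
        )
    return algo


@dataclass
class IndexDict:
    """Compact inverted index: observed hash value → sorted sketch ids."""

    algorithm: str
    sketches: list  # the indexed sketches, id = list position
    postings: dict[int, list[int]] = field(default_factory=dict)

    @property
    def n_sketches(self) -> int:
        return len(self.sketches)

    @property
    def sizes(self) -> list[int]:
        return [len(_sketch_hashes(sk)) for sk in self.sketches]

    def posting_length_sum(self) -> int:
        return sum(len(v) for v in self.postings.values())


def build_index(sketches: Sequence[PureHashSketch]) -> IndexDict:
    """Invert a family of pure-hash sketches.

    Posting lists are sorted by sketch id; only observed hashes get an
    entry (compact variant).
    """
    algo = _validate_family(sketches)
    postings: dict[int, list[int]] = {}
    for sid, sk in enumerate(sketches):  # ascending sid → sorted posting lists
        for h in _sketch_hashes(sk):
            postings.setdefault(int(h), []).append(sid)
    return IndexDict(algorithm=algo, sketches=list(sketches), postings=postings)


@dataclass
class PairwiseResult:
    """Upper-triangular all-vs-all distances."""

    names: list[str]
    results: dict[tuple[int, int], DistanceResult]

    def get(self, i: int, j: int) -> DistanceResult:
        if i == j:
            return DistanceResult(jaccard=1.0, mash_distance=0.0, shared=0, denom=0)
        return self.results[(min(i, j), max(i, j))]

    def to_rows(self) -> list[tuple[str, str, float, float, str]]:
        """TSV rows (ref, query, mash_distance, jaccard, shared/denom),
        lexicographic by (ref, query)."""
        rows = []
        for (i, j), r in self.results.items():
            rows.append((self.names[i], self.names[j], r.mash_distance, r.jaccard,
                         f"{_fmt_count(r.shared)}/{_fmt_count(r.denom)}"))
        rows.sort(key=lambda t: (t[0], t[1]))
        return rows


def _fmt_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:.2f}"


def pairwise_loop(sketches: Sequence[PureHashSketch], threads: int = 1) -> PairwiseResult:
    """Naive double loop over sketch pairs — the semantic reference."""
    algo = _validate_family(sketches)
    jac = minhash_mod.jaccard if algo == "minhash" else kssd_mod.kssd_jaccard
    pairs = [(i, j) for i in range(len(sketches)) for j in range(i + 1, len(sketches))]
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as ex:
            vals = list(ex.map(lambda p: jac(sketches[p[0]], sketches[p[1]]), pairs))
    else:
        vals = [jac(sketches[i], sketches[j]) for i, j in pairs]
    return PairwiseResult(
        names=[sk.name for sk in sketches],
        results=dict(zip(pairs, vals)),
    )


def all_vs_all(idx: IndexDict) -> PairwiseResult:
    """Accumulate per-pair shared counts from the inverted index.

    Sweeps distinct hashes in ascending order.  For MinHash a hash is
    credited to a pair only while the pair's union counter is below s
    (bottom-s' union-rank semantics); for Kssd every hash counts.  The
    output equals :func:`pairwise_loop` exactly.
    """
    n = idx.n_sketches
    shared = np.zeros((n, n), dtype=np.int64)
    union = np.zeros((n, n), dtype=np.int64)
    is_minhash = idx.algorithm == "minhash"
    s_cap = idx.sketches[0].s if is_minhash else None

    mem = np.zeros(n, dtype=bool)
    for h in sorted(idx.postings):
        ids = idx.postings[h]
        mem[:] = False
        mem[ids] = True
        in_union = mem[:, None] | mem[None, :]
        in_both = mem[:, None] & mem[None, :]
        if is_minhash:
            active = union < s_cap
            shared += in_both & active
        else:
            shared += in_both
        union += in_union

    names = [sk.name for sk in idx.sketches]
    sizes = idx.sizes
    results: dict[tuple[int, int], DistanceResult] = {}
    k = idx.sketches[0].k
    for i in range(n):
        for j in range(i + 1, n):
            sh = int(shared[i, j])
            if is_minhash:
                denom = min(s_cap, int(union[i, j]))
            else:
                denom = sizes[i] + sizes[j] - sh
            if denom == 0:
                results[(i, j)] = DistanceResult(0.0, 1.0, 0, 0)
            else:
                jv = sh / denom
                results[(i, j)] = DistanceResult(
                    jaccard=jv,
                    mash_distance=minhash_mod.mash_distance(jv, k),
                    shared=sh,
                    denom=denom,
                )
    return PairwiseResult(names=names, results=results)


def write_tsv(result: PairwiseResult, path, header: bool = True) -> None:
    """Mash dist-like TSV: ref, query, mash_distance, jaccard, shared/denom."""
    close = False
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        fh = open(path, "w")
        close = True
    else:
        fh = path
    try:
        if header:
            fh.write("ref_name\tquery_name\tmash_distance\tjaccard\tshared_denom\n")
        for ref, query, dist, jac, frac in result.to_rows():
            fh.write(f"{ref}\t{query}\t{dist:.6f}\t{jac:.6f}\t{frac}\n")
    finally:
        if close:
            fh.close()
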