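"""OrderMinHash: an edit-distance-sensitive extension of MinHash.

For each of m independent hash functions, the l k-mer occurrences with
the smallest hashes are selected and then listed in the order they occur
along the sequence.  Two sequences are similar to the extent that their
rows agree exactly — the estimator is the fraction of the m rows whose
position-ordered l-tuples of (k-mer, occurrence-index) identities match.
Because selected k-mers keep their relative order, the similarity decays
with edit distance rather than with k-mer-set distance alone.

Repeated k-mers are disambiguated by weighting: the j-th occurrence of an
identical k-mer hashes the bytes ``kmer_ascii || uint64le(j)``.  The i-th
hash function is murmur64 seeded with ``seed XOR (wang_mix(i) & 0xffffffff)``.

Sketches are per-sequence: a single order-sensitive sketch over a
multi-sequence file would mix unrelated coordinate systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hashing, seqio
from .hashing import DEFAULT_SEED

__all__ = ["OMHEntry", "OMHSketch", "omh_sketch", "omh_similarity", "rep_seed"]


def rep_seed(seed: int, i: int) -> int:
    """Seed of the i-th hash repetition, derived reproducibly from one seed."""
    return (seed ^ (hashing.wang_mix(i) & 0xFFFFFFFF)) & 0xFFFFFFFF


@dataclass(frozen=True)
class OMHEntry:
    """One selected k-mer occurrence within a row."""

    position: int
    kmer_code: int
    occurrence: int
    hash: int


@dataclass
class OMHSketch:
    """m rows of l minimal-hash k-mer occurrences in positional order."""

    k: int
    m: int
    l: int
    seed: int = DEFAULT_SEED
    name: str = ""
    rows: list[list[OMHEntry]] = field(default_factory=list)

    def row_keys(self) -> list[tuple]:
        """Per-row identity used by the similarity estimator: the
        position-ordered tuple of (k-mer, occurrence) pairs."""
        return [tuple((e.kmer_code, e.occurrence) for e in row) for row in self.rows]

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "algorithm": "omh",
            "k": self.k,
            "m": self.m,
            "l": self.l,
            "seed": self.seed,
            "name": self.name,
            "rows": [
                [[str(e.hash), seqio.decode_kmer(e.kmer_code, self.k), e.occurrence, e.position]
                 for e in row]
                for row in self.rows
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OMHSketch":
        k = int(d["k"])
        rows = [
            [OMHEntry(position=int(p), kmer_code=seqio.encode_kmer(km),
                      occurrence=int(occ), hash=int(h))
             for h, km, occ, p in row]
            for row in d["rows"]
        ]
        return cls(k=k, m=int(d["m"]), l=int(d["l"]), seed=int(d["seed"]),
                   name=d.get("name", ""), rows=rows)


def _occurrence_index(codes: np.ndarray) -> np.ndarray:
    """occ[i] = number of earlier windows with the same k-mer code."""
    n = len(codes)
    occ = np.zeros(n, dtype=np.int64)
    if n == 0:
        return occ
    _, inv = np.unique(codes, return_inverse=True)
    order = np.argsort(inv, kind="stable")  # stable → positional order within groups
    inv_sorted = inv[order]
    starts = np.concatenate(([0], np.nonzero(np.diff(inv_sorted))[0] + 1))
    group_of = np.searchsorted(starts, np.arange(n), side="right") - 1
    occ[order] = np.arange(n) - starts[group_of]
    return occ


def _weighted_key_matrix(codes: np.ndarray, occ: np.ndarray, k: int) -> np.ndarray:
    """(n, k+8) uint8 matrix of kmer ASCII bytes + occurrence uint64 LE."""
    n = len(codes)
    mat = np.empty((n, k + 8), dtype=np.uint8)
    mat[:, :k] = seqio.codes_to_ascii(codes, k)
    mat[:, k:] = occ.astype("<u8").view(np.uint8).reshape(n, 8)
    return mat


def _select_row(hashes: np.ndarray, positions: np.ndarray, l: int) -> np.ndarray:
    """Indices of the l smallest hashes (ties by position), in hash order."""
    order = np.lexsort((positions, hashes))
    return order[:l]


def omh_sketch(
    rec: seqio.SequenceRecord,
    k: int,
    m: int,
    l: int,
    seed: int = DEFAULT_SEED,
    traversal: str = "row",
    block_reps: int = 4,
    block_width: int = 1024,
) -> OMHSketch:
    """Sketch one sequence.

    ``traversal`` chooses the computation order over the m×positions grid:
    ``"row"`` hashes a full repetition at a time, ``"block"`` walks
    position blocks for groups of ``block_reps`` repetitions keeping a
    running bottom-l per repetition.  Both orders produce bit-identical
    sketches; the selection is a minimum and therefore associative.
    """
    if m < 1 or l < 1:
        raise ValueError(f"m and l must be >= 1, got m={m}, l={l}")
    if len(rec.seq) < k:
        raise ValueError(
            f"sequence {rec.id!r} shorter than k={k}; an order sketch of an "
            "empty k-mer stream is undefined"
        )
    stream = seqio.extract_kmers(rec, seqio.KmerConfig(k=k, canonical=False))
    if len(stream) == 0:
        raise ValueError(
            f"sequence {rec.id!r} has no ACGT-only window of length {k}"
        )
    codes = stream.codes
    positions = stream.positions
    occ = _occurrence_index(codes)
    keys = _weighted_key_matrix(codes, occ, k)
    n = len(codes)

    rows: list[list[OMHEntry]] = []
    if traversal == "row":
        for i in range(m):
            h = hashing.murmur64_fixed_batch(keys, rep_seed(seed, i))
            sel = _select_row(h, positions, l)
            sel = sel[np.argsort(positions[sel], kind="stable")]
            rows.append([
                OMHEntry(int(positions[t]), int(codes[t]), int(occ[t]), int(h[t]))
                for t in sel
            ])
    elif traversal == "block":
        for g0 in range(0, m, block_reps):
            reps = range(g0, min(g0 + block_reps, m))
            # running bottom-l candidates per repetition in the group
            best: dict[int, tuple[np.ndarray, np.ndarray]] = {
                i: (np.empty(0, np.uint64), np.empty(0, np.int64)) for i in reps
            }
            for c0 in range(0, n, block_width):
                chunk = slice(c0, min(c0 + block_width, n))
                kchunk = keys[chunk]
                pchunk = positions[chunk]
                ichunk = np.arange(chunk.start, chunk.stop)
                for i in reps:
                    h = hashing.murmur64_fixed_batch(kchunk, rep_seed(seed, i))
                    bh, bi = best[i]
                    ch = np.concatenate([bh, h])
                    ci = np.concatenate([bi, ichunk])
                    keep = np.lexsort((positions[ci], ch))[:l]
                    best[i] = (ch[keep], ci[keep])
            for i in reps:
                bh, bi = best[i]
                order = np.lexsort((positions[bi], bh))
                bh, bi = bh[order], bi[order]
                psel = np.argsort(positions[bi], kind="stable")
                rows.append([
                    OMHEntry(int(positions[bi[t]]), int(codes[bi[t]]),
                             int(occ[bi[t]]), int(bh[t]))
                    for t in psel
                ])
    else:
        raise ValueError(f"unknown traversal {traversal!r}")

    return OMHSketch(k=k, m=m, l=l, seed=seed, name=rec.id, rows=rows)


def omh_similarity(a: OMHSketch, b: OMHSketch) -> float:
    """Fraction of rows whose ordered (k-mer, occurrence) tuples match."""
    for attr in ("k", "m", "l", "seed"):
        if getattr(a, attr) != getattr(b, attr):
            raise ValueError(
                f"parameter mismatch: {attr}={getattr(a, attr)} vs {getattr(b, attr)}"
            )
    ka = a.row_keys()
    kb = b.row_keys()
    return sum(x == y for x, y in zip(ka, kb)) / a.m
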