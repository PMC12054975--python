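"""Synthetic genomes and brute-force oracles.

Random i.i.d. ACGT genomes, point-mutated derivatives, block-sharing
pairs and edit-load series — plus exact (enumeration-based) Jaccard and
edit-distance references.  These are first-class utilities: every
estimator in the library is validated against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import seqio
from .seqio import SequenceRecord

__all__ = [
    "MutationModel",
    "random_genome",
    "mutate",
    "random_edits",
    "block_sharing_pair",
    "exact_jaccard",
    "edit_distance",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MutationModel:
    """Independent per-base substitution model."""

    substitution_rate: float
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0, 1]")


def random_genome(length: int, seed: int, name: str | None = None) -> SequenceRecord:
    """Uniform i.i.d. ACGT sequence, deterministic per seed."""
    rng = np.random.default_rng(seed)
    seq = _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    return SequenceRecord(id=name or f"random_{length}_{seed}", seq=seq)


def mutate(rec: SequenceRecord, model: MutationModel) -> SequenceRecord:
    """Substitute each base independently (always to a different base)."""
    rng = np.random.default_rng(model.rng_seed)
    arr = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < model.substitution_rate
    idx = np.nonzero(hit)[0]
    if len(idx):
        # map base -> one of the other three, chosen uniformly
        cur = np.searchsorted(_ALPHABET, arr[idx])  # ACGT are sorted bytes
        offset = rng.integers(1, 4, size=len(idx))
        arr[idx] = _ALPHABET[(cur + offset) % 4]
    return SequenceRecord(id=f"{rec.id}_mut{model.substitution_rate}",
                          seq=arr.tobytes().decode("ascii"))


def random_edits(rec: SequenceRecord, n_edits: int, seed: int,
                 ops: tuple[str, ...] = ("sub", "ins", "del")) -> SequenceRecord:
    """Apply n random single-base edits (substitution/insertion/deletion)."""
    rng = np.random.default_rng(seed)
    seq = list(rec.seq)
    for _ in range(n_edits):
        op = ops[rng.integers(0, len(ops))]
        if op == "sub" and seq:
            i = int(rng.integers(0, len(seq)))
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[rng.integers(0, len(choices))]
        elif op == "ins":
            i = int(rng.integers(0, len(seq) + 1))
            seq.insert(i, "ACGT"[rng.integers(0, 4)])
        elif op == "del" and seq:
            i = int(rng.integers(0, len(seq)))
            del seq[i]
    return SequenceRecord(id=f"{rec.id}_edit{n_edits}", seq="".join(seq))


def block_sharing_pair(total_len: int, shared_len: int, seed: int
                       ) -> tuple[SequenceRecord, SequenceRecord]:
    """Two genomes that share one identical block and are otherwise random."""
    if shared_len > total_len:
        raise ValueError("shared block longer than the genome")
    block = random_genome(shared_len, seed * 3 + 1).seq
    a_rest = random_genome(total_len - shared_len, seed * 3 + 2).seq
    b_rest = random_genome(total_len - shared_len, seed * 3 + 3).seq
    return (
        SequenceRecord(id=f"blockA_{seed}", seq=block + a_rest),
        SequenceRecord(id=f"blockB_{seed}", seq=block + b_rest),
    )


def canonical_kmer_set(rec: SequenceRecord, k: int) -> np.ndarray:
    """Distinct canonical k-mer encodings of a record."""
    stream = seqio.extract_kmers(rec, seqio.KmerConfig(k=k, canonical=True))
    return np.unique(stream.codes)


def exact_jaccard(a: SequenceRecord, b: SequenceRecord, k: int) -> float:
    """Exact Jaccard of the two canonical k-mer sets by full enumeration."""
    sa = canonical_kmer_set(a, k)
    sb = canonical_kmer_set(b, k)
    if len(sa) == 0 and len(sb) == 0:
        return 1.0
    inter = len(np.intersect1d(sa, sb, assume_unique=True))
    union = len(sa) + len(sb) - inter
    return inter / union


def edit_distance(a: SequenceRecord | str, b: SequenceRecord | str) -> int:
    """Levenshtein distance (edlib); test oracle for the order sketches."""
    import edlib

    sa = a.seq if isinstance(a, SequenceRecord) else a
    sb = b.seq if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        return max(len(sa), len(sb))
    return int(edlib.align(sa, sb, task="distance")["editDistance"])
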