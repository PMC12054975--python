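"""Sequence input and canonical k-mer extraction.

FASTA/FASTQ files (plain or gzip, autodetected by magic bytes) are parsed
with Bio.SeqIO.  K-mers are packed 2 bits per base (A=0, C=1, G=2, T=3,
leftmost base in the most significant bits) so any k ≤ 32 fits a 64-bit
word, and by default each window is replaced by its canonical form — the
lexicographic minimum of the window and its reverse complement — which
makes downstream sketches strand-independent.  Windows containing any
non-ACGT character are dropped entirely.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "KmerConfig",
    "KmerStream",
    "reverse_complement",
    "extract_kmers",
    "encode_kmer",
    "decode_kmer",
    "read_sequences",
    "write_fasta",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")


@dataclass(frozen=True)
class KmerConfig:
    """K-mer extraction parameters.

    k must be at most 32 so the 2-bit packing fits a 64-bit integer;
    ``canonical`` selects min(kmer, revcomp(kmer)) per window.
    """

    k: int
    canonical: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 32):
            raise ValueError(f"k must be in [1, 32], got {self.k}")


@dataclass
class KmerStream:
    """Positions and packed encodings of the k-mers of one sequence.

    Iterating yields ``(position, encoded_kmer)`` pairs; positions are
    0-based window starts over half-open windows ``[i, i+k)``.
    """

    k: int
    positions: np.ndarray  # int64
    codes: np.ndarray  # uint64
    n_windows_total: int = 0  # including windows dropped for non-ACGT content

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return ((int(p), int(c)) for p, c in zip(self.positions, self.codes))

    def __len__(self) -> int:
        return len(self.codes)


# IUPAC nucleotide complement (upper-case); lowercase input is uppercased first.
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

# 256-entry tables: branchless per-base translation.
_COMP_TABLE = bytearray(range(256))
_VALID = bytearray(256)
for _b, _c in _IUPAC_COMPLEMENT.items():
    _COMP_TABLE[ord(_b)] = ord(_c)
    _VALID[ord(_b)] = 1
_COMP_TABLE = bytes(_COMP_TABLE)

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Implemented as a single 256-entry table lookup per base (branchless)
    followed by reversal.  Characters outside the IUPAC alphabet are
    rejected with the offending position.
    """
    up = seq.upper().encode("ascii", errors="replace")
    for i, b in enumerate(up):
        if not _VALID[b]:
            raise ValueError(
                f"invalid nucleotide {seq[i]!r} at position {i}: not an IUPAC code"
            )
    return up.translate(_COMP_TABLE)[::-1].decode("ascii")


def encode_kmer(kmer: str) -> int:
    """Pack an ACGT string into a 2-bit-per-base integer (MSB = leftmost)."""
    if len(kmer) > 32:
        raise ValueError("k-mer longer than 32 bases does not fit 64 bits")
    code = 0
    for i, b in enumerate(kmer.upper()):
        v = int(_CODE_LUT[ord(b)])
        if v == 255:
            raise ValueError(f"invalid base {b!r} at position {i}")
        code = (code << 2) | v
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


def _seq_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE_LUT[arr]


def extract_kmers(rec: SequenceRecord, cfg: KmerConfig) -> KmerStream:
    """All k-mer windows of a record as positions plus packed encodings.

    Windows touching any non-ACGT character are skipped.  A sequence
    shorter than k yields an empty stream.
    """
    k = cfg.k
    n = len(rec.seq)
    if n < k:
        return KmerStream(k, np.empty(0, np.int64), np.empty(0, np.uint64), 0)

    codes = _seq_codes(rec.seq)
    invalid = (codes == 255).astype(np.int64)
    codes_clean = np.where(codes == 255, 0, codes).astype(np.uint64)

    nwin = n - k + 1
    # window is valid iff it contains zero invalid bases (prefix-sum trick)
    csum = np.concatenate(([0], np.cumsum(invalid)))
    valid = (csum[k:] - csum[:-k]) == 0

    win = np.lib.stride_tricks.sliding_window_view(codes_clean, k)
    pow_fwd = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = (win * pow_fwd).sum(axis=1, dtype=np.uint64)
    if cfg.canonical:
        pow_rev = (np.uint64(4) ** np.arange(k, dtype=np.uint64))
        rc = ((np.uint64(3) - win) * pow_rev).sum(axis=1, dtype=np.uint64)
        out = np.minimum(fwd, rc)
    else:
        out = fwd

    positions = np.nonzero(valid)[0].astype(np.int64)
    return KmerStream(k, positions, out[valid], nwin)


def codes_to_ascii(codes: np.ndarray, k: int) -> np.ndarray:
    """Expand packed k-mer codes to an ``(n, k)`` uint8 ASCII matrix.

    This fixes the canonical byte serialization hashed by every sketch
    family: the k-mer's ASCII string.
    """
    codes = np.asarray(codes, dtype=np.uint64)
    shifts = np.arange(2 * (k - 1), -2, -2, dtype=np.uint64)
    idx = (codes[:, None] >> shifts[None, :]) & np.uint64(3)
    return _BASES[idx.astype(np.intp)]


def _open_maybe_gzip(path: str | Path) -> io.TextIOWrapper:
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _sniff_format(handle: io.TextIOWrapper) -> str:
    pos = handle.tell()
    first = ""
    while True:
        line = handle.readline()
        if not line:
            break
        if line.strip():
            first = line.lstrip()[0]
            break
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError("unrecognized sequence format: expected FASTA ('>') or FASTQ ('@')")


def read_sequences(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file, plain or gzipped.

    The format is sniffed from the first record marker; FASTQ quality
    strings are ignored.
    """
    with _open_maybe_gzip(path) as handle:
        try:
            fmt = _sniff_format(handle)
        except ValueError:
            if _file_is_empty(path):
                return
            raise
        for rec in SeqIO.parse(handle, fmt):
            yield SequenceRecord(id=rec.id, seq=str(rec.seq))


def _file_is_empty(path: str | Path) -> bool:
    with _open_maybe_gzip(path) as handle:
        return handle.read(1) == ""


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as multi-line FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
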