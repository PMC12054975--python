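"""Test-local naive OrderMinHash reference.

Hashes every (k-mer, occurrence) pair per repetition with the scalar
hash, sorts fully, keeps l, reorders by position.  Pure Python — shares
only the hash-function definition with the library."""

from genosketch.hashing import murmur64
from genosketch.orderminhash import rep_seed
from genosketch.seqio import KmerConfig, decode_kmer, extract_kmers


def naive_omh_rows(rec, k, m, l, seed):
    stream = extract_kmers(rec, KmerConfig(k=k, canonical=False))
    seen = {}
    entries = []  # (position, code, occ)
    for pos, code in stream:
        occ = seen.get(code, 0)
        seen[code] = occ + 1
        entries.append((pos, code, occ))
    rows = []
    for i in range(m):
        si = rep_seed(seed, i)
        hashed = [
            (murmur64(decode_kmer(code, k).encode() + occ.to_bytes(8, "little"), si),
             pos, code, occ)
            for pos, code, occ in entries
        ]
        hashed.sort(key=lambda t: (t[0], t[1]))
        sel = sorted(hashed[:l], key=lambda t: t[1])
        rows.append(tuple((code, occ) for _, _, code, occ in sel))
    return rows
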