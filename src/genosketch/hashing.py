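"""Hash functions shared by every sketch family.

Two primitives are provided:

* :func:`murmur64` — the low 64 bits of the MurmurHash3 x64_128 digest,
  used to fingerprint k-mer strings.  The byte serialization of a k-mer is
  fixed to its ASCII string so that sketches are reproducible across
  implementations and comparable across k-mer lengths.
* :func:`wang_mix` — Thomas Wang's 64-bit invertible integer mix, an
  optional fast path for integer-encoded k-mers.

A batch interface (:func:`murmur64_batch`, :func:`murmur64_fixed_batch`)
is contractually bit-identical to mapping the scalar function over the
inputs; the batch path merely vectorizes the arithmetic with numpy.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_SEED",
    "murmur64",
    "murmur128",
    "murmur64_batch",
    "murmur64_fixed_batch",
    "wang_mix",
    "wang_mix_array",
]

DEFAULT_SEED = 42

_MASK64 = 0xFFFFFFFFFFFFFFFF

_C1 = 0x87C37B91114253D5
_C2 = 0x4CF5AD432745937F


def _rotl(x: int, r: int) -> int:
    return ((x << r) | (x >> (64 - r))) & _MASK64


def _fmix64(k: int) -> int:
    k ^= k >> 33
    k = (k * 0xFF51AFD7ED558CCD) & _MASK64
    k ^= k >> 33
    k = (k * 0xC4CEB9FE1A85EC53) & _MASK64
    k ^= k >> 33
    return k


def murmur128(data: bytes, seed: int = DEFAULT_SEED) -> tuple[int, int]:
    """Full MurmurHash3 x64_128 digest of ``data`` as ``(h1, h2)``.

    ``h1`` is the first (low) 64-bit word of the 16-byte digest, matching
    the reference C implementation's ``out[0]``.
    """
    if seed < 0 or seed > 0xFFFFFFFF:
        raise ValueError(f"seed must be an unsigned 32-bit integer, got {seed}")
    length = len(data)
    nblocks = length // 16
    h1 = seed
    h2 = seed

    for b in range(nblocks):
        k1 = int.from_bytes(data[b * 16 : b * 16 + 8], "little")
        k2 = int.from_bytes(data[b * 16 + 8 : b * 16 + 16], "little")
        k1 = (k1 * _C1) & _MASK64
        k1 = _rotl(k1, 31)
        k1 = (k1 * _C2) & _MASK64
        h1 ^= k1
        h1 = _rotl(h1, 27)
        h1 = (h1 + h2) & _MASK64
        h1 = (h1 * 5 + 0x52DCE729) & _MASK64
        k2 = (k2 * _C2) & _MASK64
        k2 = _rotl(k2, 33)
        k2 = (k2 * _C1) & _MASK64
        h2 ^= k2
        h2 = _rotl(h2, 31)
        h2 = (h2 + h1) & _MASK64
        h2 = (h2 * 5 + 0x38495AB5) & _MASK64

    tail = data[nblocks * 16 :]
    k1 = 0
    k2 = 0
    tl = len(tail)
    if tl > 8:
        k2 = int.from_bytes(tail[8:], "little")
        k2 = (k2 * _C2) & _MASK64
        k2 = _rotl(k2, 33)
        k2 = (k2 * _C1) & _MASK64
        h2 ^= k2
    if tl > 0:
        k1 = int.from_bytes(tail[:8], "little")
        k1 = (k1 * _C1) & _MASK64
        k1 = _rotl(k1, 31)
        k1 = (k1 * _C2) & _MASK64
        h1 ^= k1

    h1 ^= length
    h2 ^= length
    h1 = (h1 + h2) & _MASK64
    h2 = (h2 + h1) & _MASK64
    h1 = _fmix64(h1)
    h2 = _fmix64(h2)
    h1 = (h1 + h2) & _MASK64
    h2 = (h2 + h1) & _MASK64
    return h1, h2


def murmur64(data: bytes, seed: int = DEFAULT_SEED) -> int:
    """Low 64 bits (first digest word) of MurmurHash3 x64_128."""
    return murmur128(data, seed)[0]


# ---------------------------------------------------------------------------
# Vectorized batch path.  All arithmetic is on uint64 arrays where numpy's
# modular wraparound reproduces the scalar 64-bit semantics exactly.
# ---------------------------------------------------------------------------

_U = np.uint64


def _rotl_v(x: np.ndarray, r: int) -> np.ndarray:
    return (x << _U(r)) | (x >> _U(64 - r))


def _fmix64_v(k: np.ndarray) -> np.ndarray:
    k = k ^ (k >> _U(33))
    k = k * _U(0xFF51AFD7ED558CCD)
    k = k ^ (k >> _U(33))
    k = k * _U(0xC4CEB9FE1A85EC53)
    k = k ^ (k >> _U(33))
    return k


def murmur64_fixed_batch(keys: np.ndarray, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Hash ``n`` equal-length byte keys given as an ``(n, L)`` uint8 array.

    Returns a uint64 array bit-identical to ``[murmur64(row.tobytes(), seed)
    for row in keys]``.
    """
    keys = np.ascontiguousarray(keys, dtype=np.uint8)
    if keys.ndim != 2:
        raise ValueError("keys must be a 2-D (n, L) uint8 array")
    n, length = keys.shape
    if n == 0:
        return np.empty(0, dtype=np.uint64)
    nblocks = length // 16

    h1 = np.full(n, seed, dtype=np.uint64)
    h2 = np.full(n, seed, dtype=np.uint64)
    c1 = _U(_C1)
    c2 = _U(_C2)

    # little-endian 8-byte words
    pad = (-length) % 8
    if pad:
        padded = np.zeros((n, length + pad), dtype=np.uint8)
        padded[:, :length] = keys
    else:
        padded = keys
    words = padded.view("<u8").reshape(n, -1).astype(np.uint64, copy=False)

    for b in range(nblocks):
        k1 = words[:, 2 * b].copy()
        k2 = words[:, 2 * b + 1].copy()
        k1 *= c1
        k1 = _rotl_v(k1, 31)
        k1 *= c2
        h1 ^= k1
        h1 = _rotl_v(h1, 27)
        h1 += h2
        h1 = h1 * _U(5) + _U(0x52DCE729)
        k2 *= c2
        k2 = _rotl_v(k2, 33)
        k2 *= c1
        h2 ^= k2
        h2 = _rotl_v(h2, 31)
        h2 += h1
        h2 = h2 * _U(5) + _U(0x38495AB5)

    tl = length - nblocks * 16
    if tl > 8:
        nbytes2 = tl - 8
        k2 = words[:, 2 * nblocks + 1] & _U((1 << (8 * nbytes2)) - 1)
        k2 = k2 * c2
        k2 = _rotl_v(k2, 33)
        k2 *= c1
        h2 ^= k2
    if tl > 0:
        nbytes1 = min(tl, 8)
        k1 = words[:, 2 * nblocks]
        if nbytes1 < 8:
            k1 = k1 & _U((1 << (8 * nbytes1)) - 1)
        k1 = k1 * c1
        k1 = _rotl_v(k1, 31)
        k1 = k1 * c2
        h1 ^= k1

    h1 ^= _U(length)
    h2 ^= _U(length)
    h1 += h2
    h2 += h1
    h1 = _fmix64_v(h1)
    h2 = _fmix64_v(h2)
    h1 += h2
    return h1


def murmur64_batch(items: Sequence[bytes] | Iterable[bytes], seed: int = DEFAULT_SEED) -> np.ndarray:
    """Element-wise :func:`murmur64` over a list of byte strings.

    Keys are grouped by length so each group can go through the fixed-width
    vectorized kernel; the output order matches the input order.
    """
    items = list(items)
    out = np.empty(len(items), dtype=np.uint64)
    if not items:
        return out
    by_len: dict[int, list[int]] = {}
    for i, it in enumerate(items):
        by_len.setdefault(len(it), []).append(i)
    for length, idxs in by_len.items():
        if length == 0:
            val = _U(murmur64(b"", seed))
            out[idxs] = val
            continue
        mat = np.frombuffer(b"".join(items[i] for i in idxs), dtype=np.uint8)
        mat = mat.reshape(len(idxs), length)
        out[idxs] = murmur64_fixed_batch(mat, seed)
    return out


def wang_mix(x: int) -> int:
    """Thomas Wang's 64-bit integer mix; a bijection on the 64-bit domain."""
    x &= _MASK64
    x = (~x + (x << 21)) & _MASK64
    x ^= x >> 24
    x = (x + (x << 3) + (x << 8)) & _MASK64
    x ^= x >> 14
    x = (x + (x << 2) + (x << 4)) & _MASK64
    x ^= x >> 28
    x = (x + (x << 31)) & _MASK64
    return x


def wang_mix_array(x: np.ndarray) -> np.ndarray:
    """Vectorized :func:`wang_mix` over a uint64 array."""
    x = np.asarray(x, dtype=np.uint64)
    x = (~x) + (x << _U(21))
    x = x ^ (x >> _U(24))
    x = x + (x << _U(3)) + (x << _U(8))
    x = x ^ (x >> _U(14))
    x = x + (x << _U(2)) + (x << _U(4))
    x = x ^ (x >> _U(28))
    x = x + (x << _U(31))
    return x
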