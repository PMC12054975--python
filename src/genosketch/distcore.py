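"""Sorted-set intersection engine shared by the hash-set sketches.

Two interchangeable routines compute the intersection size of two sorted,
duplicate-free 64-bit hash lists: a plain two-pointer merge and a blocked
variant that compares fixed-width blocks and advances the list whose block
maximum is smaller.  The blocked path is an acceleration only — it must
return exactly the merge count on every input, and the test suite holds it
to that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DistanceResult", "intersect_count", "mash_distance"]

DEFAULT_BLOCK = 8


@dataclass(frozen=True)
class DistanceResult:
    """Similarity between two sketches.

    ``jaccard`` is ``shared / denom`` (0 when the denominator is 0) and
    ``mash_distance`` its Mash-model transform; ``shared`` and ``denom``
    are exact counts for the hash-set sketches and estimates for
    HyperLogLog.
    """

    jaccard: float
    mash_distance: float
    shared: float
    denom: float


def mash_distance(j: float, k: int) -> float:
    """Mash distance D = -(1/k)·ln(2j/(1+j)); 0 at j=1, clamped to 1 at j=0."""
    if not (0.0 <= j <= 1.0):
        raise ValueError(f"jaccard must be in [0, 1], got {j}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if j == 0.0:
        return 1.0
    if j == 1.0:
        return 0.0
    d = -np.log(2.0 * j / (1.0 + j)) / k
    return float(min(d, 1.0))


def _check_sorted_distinct(x: np.ndarray, name: str) -> None:
    if len(x) > 1 and not np.all(x[:-1] < x[1:]):
        raise ValueError(f"{name} is not strictly increasing")


def _merge_count(a: np.ndarray, b: np.ndarray) -> int:
    i = j = c = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        if a[i] < b[j]:
            i += 1
        elif a[i] > b[j]:
            j += 1
        else:
            c += 1
            i += 1
            j += 1
    return c


def _block_count(a: np.ndarray, b: np.ndarray, block: int) -> int:
    i = j = c = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        ablock = a[i : i + block]
        bblock = b[j : j + block]
        amax = ablock[-1]
        bmax = bblock[-1]
        # count matches between the two blocks, then advance past the
        # smaller block maximum (elements beyond it can still match later)
        c += int(np.isin(ablock, bblock, assume_unique=True).sum())
        if amax < bmax:
            i += len(ablock)
            # drop b elements <= amax: they cannot match any remaining a
            j += int(np.searchsorted(bblock, amax, side="right"))
        elif bmax < amax:
            j += len(bblock)
            i += int(np.searchsorted(ablock, bmax, side="right"))
        else:
            i += len(ablock)
            j += len(bblock)
    return c


def intersect_count(
    a: np.ndarray,
    b: np.ndarray,
    method: str = "block",
    block: int = DEFAULT_BLOCK,
    check: bool = False,
) -> int:
    """|a ∩ b| for sorted distinct uint64 arrays.

    ``method`` selects the two-pointer ``"merge"`` reference or the
    ``"block"`` variant; ``check=True`` validates sortedness first
    (debug mode), otherwise inputs are trusted.
    """
    a = np.asarray(a, dtype=np.uint64)
    b = np.asarray(b, dtype=np.uint64)
    if check:
        _check_sorted_distinct(a, "a")
        _check_sorted_distinct(b, "b")
    if len(a) == 0 or len(b) == 0:
        return 0
    if method == "merge":
        return _merge_count(a, b)
    if method == "block":
        if block < 1:
            raise ValueError("block width must be >= 1")
        return _block_count(a, b, block)
    raise ValueError(f"unknown intersection method {method!r}")
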