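# Methods

## Canonical k-mers and hashing

All sketch families operate on k-mers (k ≤ 32, default 21) packed two
bits per base (A=0, C=1, G=2, T=3, leftmost base in the most significant
bits). Except for OrderMinHash, a window is replaced by its canonical
form — the lexicographic minimum of the window and its reverse
complement — which with this encoding coincides with the numeric minimum
of the two packed codes; sketches are therefore strand-independent.
Windows containing any non-ACGT character are dropped whole, and
lowercase input is uppercased first. Both conventions follow the Mash
lineage so that sketches are comparable with the wider ecosystem.
`reverse_complement` accepts the full IUPAC alphabet through a 256-entry
translation table (one branchless lookup per base) and rejects anything
else, naming the offending position.

The hash of a k-mer is the low 64 bits of the MurmurHash3 x64_128 digest
of its ASCII string, seed 42 by default. The ASCII string is the one
canonical byte serialization: hashing a decoded packed code gives the
same value as hashing the original string, and sketches built with the
same seed are bit-identical across platforms. Conformance with the
reference MurmurHash3 is pinned in the test suite by the SMHasher
verification procedure (digesting 256 canonical keys and checking the
folded 32-bit constant). Which 64 bits of the 128-bit digest to keep is
a convention; we fix the first output word, as Mash does. A batch
interface vectorizes the same arithmetic with numpy uint64 wraparound
and is contractually bit-identical to the scalar function — the library
treats vectorization as an optimization that must never change results.
Thomas Wang's 64-bit mix is provided as a distinct integer-hash variant
(bijective, so it cannot create collisions on packed codes), but the
default pipeline always hashes strings so sketches remain comparable
across k.

## KMV MinHash

A sketch keeps the s smallest distinct hash values seen so far (bottom-s
/ KMV). Because "bottom-s of everything seen" is an associative,
commutative reduction, streaming updates, batch builds, merges and any
input order produce identical sketches; duplicate k-mers collapse (set
semantics). Default s = 1000, the Mash default — standard error of the
Jaccard estimate is about √(J(1−J)/s) ≈ 1.6% at J = 0.5.

Jaccard between two sketches uses the Mash estimator: take the
s' = min(s, |A_sk ∪ B_sk|) smallest values of the merged hash lists and
count those present in both; J ≈ x/s'. The min with the union size
handles genomes with fewer than s distinct k-mers, in which case the
estimate is exact. Mash distance D = −(1/k)·ln(2J/(1+J)), clamped to 1
when J = 0 and defined as 0 when J = 1. Under the Poisson approximation
a per-base substitution rate r gives J ≈ (1−r)^k/(2−(1−r)^k) and
D ≈ −ln(1−r) ≈ r, which is what the mutate-and-recover calibration
checks (±0.01 at r ∈ {0.01, 0.05}).

Shared counts are produced by sorted-list intersection. Two routines are
provided: a two-pointer merge (reference) and a blocked variant (default
width 8) that compares block maxima to advance whole blocks at a time.
The blocked path is an acceleration with an exactness obligation — every
input must give the merge count — enforced by randomized equivalence
tests rather than assumed.

## OrderMinHash

For each of m hash functions (default m = 256), the l k-mer occurrences
(default l = 2) with smallest hash are selected and then re-sorted by
position; similarity is the fraction of rows whose position-ordered
(k-mer, occurrence-index) tuples match exactly (all-or-nothing row
equality). Repeated k-mers are distinguished by occurrence weighting:
the j-th occurrence of an identical k-mer hashes
`kmer_ascii || uint64le(j)`. The i-th hash function is murmur64 seeded
with `seed XOR (wang_mix(i) & 0xffffffff)`, so all m functions derive
reproducibly from one seed.

Design choices made here: OrderMinHash uses forward (non-canonical)
k-mers — the sketch is a proxy for edit distance, which is defined on a
fixed strand, and canonicalization would splice reverse-complement
content into the positional order. Sketches are strictly per-sequence;
a single order-sensitive sketch spanning a multi-record file would
concatenate unrelated coordinate systems. Ties between equal hashes are
broken by position, making selection a total order.

The m×positions grid can be traversed row-wise or in position-blocks for
groups of 4 repetitions (a cache-reuse pattern); because bottom-l
selection under a total order is associative, any traversal yields the
identical sketch, and the test suite asserts bit-equality between the
two implementations rather than trusting the argument.

## Kssd

A dictionary is a Fisher–Yates shuffle of the 4^L codes of a length-L
substring (L = `half_k`, default 6), produced by numpy's PCG64 generator
seeded explicitly — the PRNG is pinned by name so dictionaries are
portable. A k-mer is selected iff the code of its central substring
(start offset (k−L)//2) ranks below 4^(L−d) in the shuffle
(d = `drlevel`, default 3), i.e. a deterministic 1/4^d fraction of the
k-mer space. Any fixed subset of that size would work; the
prefix-of-the-shuffle rule is fixed for reproducibility. Sketches store
the full packed canonical k-mer (not the reduced remainder) — simpler,
and intersection semantics are unchanged for a fixed dictionary. A
sha256-derived `dict_id` over (L, d, seed, perm checksum) binds sketches
to their dictionary; comparing sketches across dictionaries is an error.

Because both genomes are filtered by the same dictionary, Jaccard over
the selected sets is an unbiased estimate of the full-set Jaccard and is
computed exactly by sorted intersection: J = |A∩B|/(|A|+|B|−|A∩B|). The
Mash-distance transform applies unchanged.

The compact map dictionary holds only the 4^(L−d) valid codes. Its
contract — agreement with the full permutation array on every code, and
bit-identical sketches — is tested exhaustively over the code space for
L ≤ 6.

## HyperLogLog

2^p one-byte registers (default p = 14, 16 KiB per sketch; 6 bits would
suffice, bytes are kept for simplicity). A hash routes to the register
addressed by its top p bits; the register keeps the maximum rank =
leading zeros of the remaining 64−p bits, plus one (an all-zero suffix
yields the maximal rank 64−p+1). The estimator is the bias-corrected
original HyperLogLog: α_m·m²/Σ 2^(−M_j), with linear counting
m·ln(m/V) when the raw estimate is ≤ 2.5m and V registers are still
zero; with 64-bit hashes no large-range correction is needed. Expected
relative error is ≈ 1.04/√m ≈ 0.81% at p = 14. The estimator variant is
pinned; the suite checks calibration (mean relative error ≤ 2% across
n = 100 to 100,000) and cross-checks the vectorized register pipeline
against a deliberately branchy scalar reference, which also discharges
the branch-free-comparison obligation as an equivalence rather than an
instruction choice.

Merging takes register-wise maxima — the join of the register lattice —
so merge(sketch(X), sketch(Y)) equals sketch(X∪Y) exactly, register for
register. Jaccard uses inclusion–exclusion over the three cardinalities,
clamped to [0, 1].

## Inverted-index all-vs-all

For pure-hash sketches (MinHash, Kssd) the index maps each observed hash
value to the sorted list of sketches containing it; a single ascending
sweep over distinct hashes accumulates per-pair shared counts. The Mash
estimator's union denominator is handled by union-rank streaming: a pair
stops crediting shared hashes once its union counter reaches s, which
reproduces "shared among the bottom-s' of the union" exactly. Pair
counters are dense (n×n) numpy matrices — at the scale where the index
is preferable the n² counter cost is negligible next to the postings —
rather than a sparse pair-keyed map. The index is an acceleration only:
tests require bit-identical results to the naive pairwise loop for both
families, including the small-s regime where the union cap binds. The
compact index stores no entry for unobserved hashes, so memory grows
with distinct observed hashes, never with the 2^64 hash space.

The pairwise engine accepts a thread count (pairs are independent and
results are collected positionally, so output is identical for any
worker count); the index sweep is single-threaded.

## Synthetic data and what it shows

The fixture generator emulates the simplest divergence process relevant
to the estimators: uniform i.i.d. ACGT genomes (default lengths 1 kb to
100 kb depending on the check), independent per-base substitutions at a
given rate (always to a different base), mixed single-base edit loads
for the order sketches, and pairs sharing one identical block. Distance
calibration uses substitution-only divergence, matching the Poisson
model behind the Mash formula; indel-bearing pairs appear only in the
OrderMinHash monotonicity checks. Real genomes add repeats, skewed base
composition and structural variation, which affect k-mer uniqueness and
hence estimator variance — passing tests demonstrate correctness of the
algorithms and calibration under the stated model, not accuracy claims
for any particular taxon. Brute-force oracles (full k-mer enumeration,
exact Jaccard via two independent set implementations, edlib edit
distance cross-checked against a small DP) are computed at scales where
enumeration is cheap.

Problem sizes used by the default suite and the acceptance script —
200 genome pairs at 100 kb for the KMV error envelope, 20 replicates per
substitution rate, 20 seeds per HyperLogLog cardinality point, ten 5 kb
genomes for index equivalence — were chosen to give the statistical
assertions comfortable power (≥ 4σ margins on binomial bounds) while
keeping a full run in the low minutes on one core.

## Numerical conventions and edge cases

* Empty union (two empty sketches): Jaccard reported as 0 with distance
  1 and denominator 0 — no evidence of similarity is not similarity;
  the `jaccard == shared/denom` identity is maintained whenever
  denom > 0.
* Sequences shorter than k: MinHash/Kssd/HLL updates are no-ops;
  OrderMinHash raises, as an order sketch of an empty k-mer stream is
  undefined.
* Hash ties across distinct k-mers are theoretically possible and
  handled: sets deduplicate values, OrderMinHash breaks ties by
  position.
* Sortedness of hash lists is trusted in the fast path; a debug mode
  validates it and raises.
* Serialization stores 64-bit values as decimal strings inside JSON
  lines, avoiding double-precision truncation in permissive JSON
  readers; round-trips are bit-exact. HyperLogLog registers serialize as
  base64.
* Seeds: the hash seed (default 42) and the Kssd dictionary seed are
  configuration, surfaced everywhere; no other randomness exists outside
  the fixture generator, whose seeds are explicit arguments.

## Known limitations

* KMV Jaccard between genomes of very different sizes inherits the Mash
  estimator's containment blindness; no containment index is provided.
* The Mash-distance ↔ substitution-rate identity degrades for r ≳ 0.1
  (k-mer survival saturates at k = 21).
* OrderMinHash similarity is a row-equality estimator; per-element
  partial credit (and hence finer resolution at high divergence) is out
  of scope.
* The inverted-index sweep materializes n×n counters; for very large
  collections a sparse accumulation would be preferable.
* No p-values on distances, and no compatibility with Mash's binary
  `.msh` container.
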