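# Methods

## The model

`panmemo` indexes a pangenome `G = {G1, ..., Gt}` relative to one *pivot*
genome `G1`.  All queries are for substrings of the pivot: given a pivot
window `[i, j)` and a length `k`, a **membership query** reports, for every
k-mer start `x ∈ [i, j-k]`, which genomes contain the k-mer (on either
strand), and a **conservation query** reports how many genomes contain it,
an integer in `[1, t]` since the pivot always contains its own k-mers.
Because the index stores match *intervals* rather than k-mers, a single
index answers these queries for every k simultaneously.

### Matching statistics and MEMs

For the pivot sequence `P[1..m]` against a target text `T`, the matching
statistics are `MS[j]` = length of the longest suffix of `P[1..j]`
occurring in `T`.  Consecutive values satisfy the sawtooth bound
`MS[j] - MS[j-1] <= 1`: extending the prefix by one character can extend
the best match by at most one character.  A position `j` with
`MS[j] >= MS[j+1]` (or `j = m`) is a *peak*, and peaks map one-to-one to
maximal exact matches (MEMs): the peak of value `ell` yields the half-open
pivot interval `[j+1-ell, j+1)`.  A k-mer occurs in the target genome iff
its interval is contained in some MEM — equivalently iff
`MS[x+k-1] >= k`.

The target text of a genome concatenates every sequence and its reverse
complement, each followed by a separator, so matches are strand-symmetric
and never cross sequence boundaries.  The MS engine is a suffix automaton
of the target text: linear-time construction, then a single streaming scan
of the pivot yields the longest-match length at every position.  The
automaton operates on integer tokens; each separator occurrence and each
non-ACGT residue gets a *unique* token, which makes them unmatchable by
construction (including N-vs-N).  The engine is cross-checked against a
quadratic brute-force scan on thousands of random strings.

### Overlap records

The index does not store MEMs but the *overlaps between consecutive MEMs*:
for the consecutive pair `[s_a, e_a)`, `[s_b, e_b)` the record is
`(s_b, e_a)`.  A k-mer `[x, x+k)` with `x < s_b` and `x + k > e_a`
(overhang on both sides) fits in neither MEM of the pair and no other MEM
can span it, so it is absent.  The query is a marking scan: each record
`(s, e)` clears the k-mer starts in `[e-k+1, s)`.

Three boundary encodings make the published scan literally correct on all
inputs:

* adjoining MEMs produce a zero-length record (`start == end`);
* consecutive MEMs separated by an uncovered stretch (possible around
  ambiguous residues) produce an *inverted* record (`start > end`) which
  fires for every k, correctly marking the uncovered positions absent;
* sentinel records `(first_mem_start, 0)` and `(pivot_len, last_mem_end)`
  mark k-mers extending past the first or last MEM as absent; a track with
  no MEMs collapses to the single record `(pivot_len, 0)` (everything
  absent).

### Order-MEMs and conservation

Stacking the per-genome MS vectors gives a matrix `L` with `t' = t - 1`
rows (the pivot is not compared against itself; reported conservation adds
1 for the pivot).  Sorting every column of `L` in descending order gives
the order-MS matrix `O`.  Each row of `O` again satisfies the sawtooth
bound — sorting preserves it — so the same peak-to-MEM mapping yields
*order-MEMs*: containment in an order-r MEM certifies presence in at least
r non-pivot genomes, and `O[r][x+k-1] >= k` iff at least r genomes match.
Conservation is therefore `(smallest failing order) - 1`, or `t'` when no
order fails; the failing set is upward-closed in r, which also licenses
early stopping / binary search over ranks (property-tested).

### Quantile sampling

When decile resolution suffices, only the order rows at the quantiles of
`t'` are kept: rank `x = min{ x : x >= q * t' }` per quantile q.  For 89
samples and deciles these are ranks 9, 18, 27, ..., 89.  The computation
uses exact rational arithmetic; a binary-float ceiling would, e.g., return
10 instead of 9 for `0.1 * 90`.  A quantile query reports the largest
retained rank whose track does not fail — exactly the full-resolution
count floored onto the retained ranks (property-tested), labelled with its
quantile ("30%", ..., "100%", or below-lowest).

### k-range subsetting

Restricting queries to `k <= k_max` allows discarding overlap records with
`end - start > k_max - 2`: straddling a record of length L requires
`k >= L + 2`.  Restricting to `k >= k_min` allows discarding MEMs shorter
than `k_min` from MEM-flavor indexes.  Both rules are provably lossless
for the permitted k and are verified against unfiltered queries.  (A
looser count — dropping length >= k_max + 1 — also appears plausible from
a closed-interval reading; the implemented bound is the one that follows
from the half-open record geometry.)

## On-disk format

Records are four columns — dictionary-encoded chromosome, unsigned start,
end, annotation (genome id or order rank) — sorted by (chrom, start, end,
annotation) and written to Apache Parquet with the ZSTD codec via pyarrow.
Sorting brings redundant coordinates into proximity, which is what makes
columnar compression effective; the test suite verifies the compressed
index is smaller than the equivalent uncompressed BED text for >= 10^4
records.  Index metadata (flavor, pivot name and sequence lengths, genome
roster, retained orders and quantile labels, k-range, schema version)
lives in the Parquet footer's key-value metadata, making the file
self-describing.  Row-group size defaults to 16 MiB — appropriate for
genomes held in memory; the writer accepts larger targets for bigger
collections.  Region retrieval keeps overlap records with
`start > i and end < j` plus all sentinels (a record can only affect
k-mer starts in `[end-k+1, start)`), and MEM records overlapping the
window; queries over the fetched subset are property-tested equal to
full-scan queries.

## Synthetic pangenomes

The generator draws a uniform-ACGT pivot and derives each other genome
independently (star phylogeny): per-base substitutions to a different base
at `snp_rate`, and insertions/deletions at `indel_rate` with lengths
uniform in `1..max_indel_len` (default 10).  Defaults: 5 kb pivot, 4
genomes, `snp_rate = 0.01`, `indel_rate = 0.001` — divergence in the range
of intra-species pangenomes, dense enough to exercise every boundary case
(gaps, sentinels, order ties).  Deterministic under its seed, emitting a
JSON manifest of applied mutations.  It does **not** model coalescent
structure, structural variation, repeats or sequencing error, so passing
tests demonstrate algorithmic correctness of the index and queries, not
performance or robustness on repeat-rich real assemblies.

## The brute-force oracle

The independent ground truth is a canonical-k-mer comparator: each
genome's set of canonical k-mers (lexicographic min of k-mer and reverse
complement; k-mers containing non-ACGT excluded), membership by set
lookup, conservation by summation.  It shares no code with the index path
beyond `revcomp`.  The central correctness claim — overlap-record route ≡
MEM-containment route ≡ oracle, position-by-position — is asserted over a
corpus of 100 seeded pangenomes (2–8 genomes, 2–10 kb pivots over 1–3
sequences, SNP rates 0.005–0.02, indel rates 0.0005–0.002) for
k ∈ {1, 2, 4, 11, 21, 31, 51}; these sizes keep the full suite in the
minutes range on one core while covering every interacting feature
(multi-sequence pivots, indel-induced gaps, order ties, empty tracks).

## Numerical and design choices

* Coordinates are 0-based half-open everywhere, including the CLI.
* Zero MS values are never peaks (a zero-length match is not a MEM).
* The marking matrix is allocated over valid k-mer starts `[i, j-k]` only,
  and marking intervals are clipped to it; fetched records may extend
  beyond the window.
* A conservation column in which no order fails means the k-mer is present
  in all `t'` genomes; the count is `t'` (a naive argmax over an all-zero
  column would return 0).
* `include_pivot` defaults to true so reported counts lie in `[1, t]`; the
  raw other-genome count is always available.
* Lowercase (soft-masked) input is uppercased, not excluded; non-ACGT
  residues are unmatchable on both pattern and text sides.
* A pivot-only pangenome (`t' = 0`) reports conservation 1 everywhere.

## Limitations

Single pivot per index; queries are limited to pivot substrings.  The MS
engine holds the target text and automaton in memory (fine up to tens of
Mb per genome; pangenome-scale deployments would substitute a compressed
MS engine behind the same contract).  Order tracks deliberately destroy
per-genome attribution.  Quantile indexes answer only quantile queries.
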