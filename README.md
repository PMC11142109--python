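# panmemo

A compact pangenome index built on maximal exact matches (MEMs) that
answers **arbitrary-length k-mer queries** anchored to a pivot genome:

* **membership** — for each k-mer of a pivot window, which genomes of the
  pangenome contain it (on either strand);
* **conservation** — in how many genomes it occurs, an integer in `[1, t]`;
* **quantile conservation** — the same at decile (or any quantile)
  resolution from a much smaller, lossily subsampled index.

Unlike k-mer or de Bruijn indexes, which fix k at build time, the index
stores match *intervals*, so one index serves every k.  It is intended for
researchers studying sequence conservation across genome collections —
and, through its synthetic-pangenome generator, as a fully self-contained
testbed for interval-based pangenome indexing.

## The method in brief

For pivot `P[1..m]` and a target genome's text `T` (both strands,
separator-delimited), the matching statistics `MS[j]` give the length of
the longest suffix of `P[1..j]` occurring in `T`; they obey the sawtooth
bound `MS[j] − MS[j−1] ≤ 1`.  Positions with `MS[j] ≥ MS[j+1]` (peaks) map
one-to-one to MEMs `[j+1−ℓ, j+1)`.  A k-mer `[x, x+k)` occurs in the
target iff it is contained in a MEM; equivalently, it is *absent* iff it
spans the overlap `(s_b, e_a)` of two consecutive MEMs with overhang on
both sides (`x < s_b` and `x+k > e_a`).  The index stores only these
overlap records, columnar-compressed (Parquet + ZSTD).

For conservation, the per-genome MS vectors are stacked into a matrix and
each column sorted in descending order.  Sorting preserves the sawtooth
property row-wise, so each sorted row again yields MEMs — *order-MEMs* —
and containment in an order-r MEM certifies presence in ≥ r non-pivot
genomes.  The conservation count is the largest non-failing order (plus
one for the pivot).  Keeping only the order rows at quantile ranks
(`min{x : x ≥ q·t'}`; ranks 9, 18, …, 89 for deciles of 89 samples) gives
the lossy decile index.

Details, boundary conventions and design rationale: `docs/methods.md`.

## Worked example

Simulate a 5-genome pangenome (2 kb pivot, 1% SNPs, 0.1% indels), index
it for conservation, and query 31-mers over a 200 bp window:

```sh
panmemo simulate --length 2000 --genomes 5 --snp-rate 0.01 \
    --indel-rate 0.001 --seed 7 --out-dir pan
panmemo index --pivot pan/pivot.fa \
    --genomes pan/genome1.fa --genomes pan/genome2.fa \
    --genomes pan/genome3.fa --genomes pan/genome4.fa \
    --flavor conservation --out cons.parquet
panmemo query --index cons.parquet --region piv_seq0:500-700 \
    --k 31 --type conservation --out cons.tsv
```

The index step prints `wrote 438 records (conservation-overlap) to
cons.parquet`, and `cons.tsv` begins:

```
chrom	start	count
piv_seq0	500	4
piv_seq0	501	4
piv_seq0	502	4
```

Each row is one 31-mer start (0-based) with the number of genomes, pivot
included, containing that 31-mer.  Over the 170 starts of this window the
counts distribute as `{1: 3, 2: 28, 3: 35, 4: 59, 5: 45}`: 45 of the
31-mers are conserved in all five genomes, while three (those crossing the
densest mutation cluster) occur in the pivot alone.

The same index drives a stacked-bar conservation plot
(`panmemo viz --index cons.parquet --region piv_seq0:0-2000 --k 31
--bins 50 --out cons.png`; the white area above each stack is the
fraction of fully conserved k-mers), and `panmemo export-bed` dumps the
records as a BED4 track.  Add `--quantiles deciles` at index time for the
lossy decile index (`--type quantile` at query time); `--k-max`/`--k-min`
shrink the index by restricting the permitted k range.  Everything is
also available as a library (`panmemo.build_index_records`,
`panmemo.membership`, `panmemo.conservation`, …), with all coordinates
0-based half-open.

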