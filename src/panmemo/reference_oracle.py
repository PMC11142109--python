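"""Brute-force canonical-k-mer oracles used as ground truth in tests.

A k-mer's canonical form is the lexicographic minimum of the k-mer and its
reverse complement, which makes presence strand-symmetric: a k-mer occurs
on either strand of a genome iff its canonical form is in the genome's
canonical k-mer set.  This matches the index's strand convention (target
texts contain both strands), and the property tests confirm the two
conventions agree.  k-mers containing non-ACGT symbols are excluded from
the sets and treated as absent everywhere except the pivot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .query_engine import ConservationResult, MembershipResult, QueryRegion
from .seq_io import GenomeSequence, revcomp

__all__ = ["KmerSet", "build_kmer_set", "oracle_membership", "oracle_conservation"]

_ACGT = frozenset("ACGT")


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerSet:
    """All canonical k-mers of one genome (both strands implied)."""

    genome_name: str
    k: int
    kmers: frozenset[str]

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.kmers


def build_kmer_set(genome: GenomeSequence, k: int) -> KmerSet:
    if k < 1:
        raise ValueError("k must be >= 1")
    kmers: set[str] = set()
    for _, seq in genome.sequences:
        ok = np.fromiter((c in _ACGT for c in seq), dtype=bool, count=len(seq))
        for x in range(len(seq) - k + 1):
            if ok[x : x + k].all():
                kmers.add(canonical(seq[x : x + k]))
    return KmerSet(genome.name, k, frozenset(kmers))


def oracle_membership(
    pivot: GenomeSequence,
    others: list[GenomeSequence],
    region: QueryRegion,
    kmer_sets: list[KmerSet] | None = None,
) -> MembershipResult:
    """Presence of every pivot k-mer in the window, per non-pivot genome,
    by direct canonical-k-mer set lookup."""
    k = region.k
    if kmer_sets is None:
        kmer_sets = [build_kmer_set(g, k) for g in others]
    seq = pivot.sequence(region.chrom)
    matrix = np.zeros((region.n_starts, len(others)), dtype=bool)
    for row, x in enumerate(range(region.i, region.j - k + 1)):
        kmer = seq[x : x + k]
        if not _ACGT.issuperset(kmer):
            continue  # ambiguous pivot k-mer: absent everywhere
        for g, ks in enumerate(kmer_sets):
            matrix[row, g] = kmer in ks
    return MembershipResult(region, tuple(g.name for g in others), matrix)


def oracle_conservation(
    pivot: GenomeSequence,
    others: list[GenomeSequence],
    region: QueryRegion,
    include_pivot: bool = True,
    kmer_sets: list[KmerSet] | None = None,
) -> ConservationResult:
    """Number of genomes containing each pivot k-mer: the per-genome oracle
    memberships summed, plus one for the pivot when requested."""
    mem = oracle_membership(pivot, others, region, kmer_sets)
    counts_others = mem.matrix.sum(axis=1).astype(np.int64)
    return ConservationResult(region, len(others), counts_others, include_pivot)
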