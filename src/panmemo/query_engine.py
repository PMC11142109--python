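"""Membership, conservation and quantile-conservation queries.

All queries are anchored to the pivot: the caller names a pivot sequence,
a half-open window ``[i, j)`` and a k-mer length k, and gets one result
row per k-mer start ``x`` in ``[i, j - k]``.

The overlap-record route implements the marking scan: a record ``(s, e)``
witnesses the absence of every k-mer with ``x < s`` and ``x + k > e`` —
equivalently it clears starts in ``[e - k + 1, s)`` — because such a k-mer
is contained in neither of the two consecutive MEMs that produced the
record, and no other MEM can span it.  The MEM-containment route tests the
same thing directly: a k-mer is present iff some MEM contains it.  Both
routes give identical answers; the overlap route is what the compact index
stores.

Conservation works on order tracks: track r fails at start x when the
k-mer straddles one of its records, which happens exactly when the k-mer
occurs in fewer than r non-pivot genomes.  The failing set is therefore
upward-closed in r, the count of other genomes containing the k-mer is
(smallest failing order) - 1, and scanning orders in any sequence with
early stopping at the first decidable rank gives the same answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .mem_core import MemInterval, OverlapRecord

__all__ = [
    "QueryRegion",
    "MembershipResult",
    "ConservationResult",
    "membership",
    "membership_via_mems",
    "conservation",
    "quantile_conservation",
]


@dataclass(frozen=True)
class QueryRegion:
    """A query window: pivot sequence name, half-open ``[i, j)``, k."""

    chrom: str
    i: int
    j: int
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.j - self.i < self.k:
            raise ValueError(
                f"region [{self.i},{self.j}) shorter than k={self.k}"
            )

    @property
    def starts(self) -> np.ndarray:
        """Valid k-mer start offsets: ``i .. j - k`` inclusive."""
        return np.arange(self.i, self.j - self.k + 1)

    @property
    def n_starts(self) -> int:
        return self.j - self.k - self.i + 1


@dataclass(frozen=True)
class MembershipResult:
    """Per-start, per-genome presence.  ``matrix[x - i, g]`` is True when
    the k-mer starting at pivot offset x occurs in non-pivot genome g; the
    pivot itself is an implicit all-True column."""

    region: QueryRegion
    genome_names: tuple[str, ...]
    matrix: np.ndarray  # bool, shape (n_starts, t')

    @property
    def starts(self) -> np.ndarray:
        return self.region.starts


@dataclass(frozen=True)
class ConservationResult:
    """Per-start conservation.  ``counts`` includes the pivot when
    ``include_pivot`` (values in [1, t]); ``counts_others`` is the raw
    non-pivot count in [0, t'].  For quantile queries ``labels`` carries
    the certified quantile per start ('<10%' below the lowest retained
    rank)."""

    region: QueryRegion
    t_prime: int
    counts_others: np.ndarray
    include_pivot: bool = True
    labels: tuple[str, ...] | None = None

    @property
    def counts(self) -> np.ndarray:
        return self.counts_others + 1 if self.include_pivot else self.counts_others

    @property
    def starts(self) -> np.ndarray:
        return self.region.starts


def _check_k_bounds(region: QueryRegion, k_max: int | None, k_min: int | None) -> None:
    if k_max is not None and region.k > k_max:
        raise ValueError(f"k={region.k} exceeds index k_max={k_max}")
    if k_min is not None and region.k < k_min:
        raise ValueError(f"k={region.k} below index k_min={k_min}")


def _mark_absent(
    records: Iterable[OverlapRecord],
    region: QueryRegion,
    n_tracks: int,
    track_of: dict[int, int] | None = None,
) -> np.ndarray:
    """Boolean (n_starts, n_tracks) matrix of *absence* marks from the
    overlap-record scan, clipped to the region's valid k-mer starts."""
    i, k = region.i, region.k
    last_start = region.j - k  # inclusive
    absent = np.zeros((region.n_starts, n_tracks), dtype=bool)
    for r in records:
        if r.chrom != region.chrom:
            continue
        lo = r.end - (k - 1)
        hi = r.start
        if lo >= hi:
            continue
        lo = max(lo, i)
        hi = min(hi, last_start + 1)
        if lo >= hi:
            continue
        col = r.annotation if track_of is None else track_of[r.annotation]
        absent[lo - i : hi - i, col] = True
    return absent


def membership(
    records: Sequence[OverlapRecord],
    region: QueryRegion,
    genome_names: Sequence[str],
    k_max: int | None = None,
) -> MembershipResult:
    """Membership query over overlap records (the marking scan).

    Starts all-present, then each straddled record clears the k-mer starts
    it witnesses as absent for its genome.
    """
    _check_k_bounds(region, k_max, None)
    absent = _mark_absent(records, region, len(genome_names))
    return MembershipResult(region, tuple(genome_names), ~absent)


def membership_via_mems(
    mems: Sequence[MemInterval],
    region: QueryRegion,
    genome_names: Sequence[str],
    k_min: int | None = None,
) -> MembershipResult:
    """Membership query by direct MEM containment: a k-mer is present in a
    genome iff one of that genome's MEMs contains its interval."""
    _check_k_bounds(region, None, k_min)
    i, k = region.i, region.k
    last_start = region.j - k
    present = np.zeros((region.n_starts, len(genome_names)), dtype=bool)
    for m in mems:
        if m.chrom != region.chrom:
            continue
        lo = max(m.start, i)
        hi = min(m.end - k, last_start) + 1  # starts with x + k <= m.end
        if lo < hi:
            present[lo - i : hi - i, m.annotation] = True
    return MembershipResult(region, tuple(genome_names), present)


def conservation(
    records: Sequence[OverlapRecord],
    region: QueryRegion,
    t_prime: int,
    include_pivot: bool = True,
    k_max: int | None = None,
) -> ConservationResult:
    """Conservation query over order-overlap records.

    For each start the failing orders are exactly the ranks r greater than
    the number of other genomes containing the k-mer, so the reported
    non-pivot count is (smallest failing order) - 1, or t' when no order
    fails.
    """
    _check_k_bounds(region, k_max, None)
    if t_prime == 0:  # pivot-only pangenome: the pivot is the only witness
        counts_others = np.zeros(region.n_starts, dtype=np.int64)
        return ConservationResult(region, t_prime, counts_others, include_pivot)
    track_of = {r: r - 1 for r in range(1, t_prime + 1)}
    failing = _mark_absent(records, region, t_prime, track_of)
    any_fail = failing.any(axis=1)
    first_fail = failing.argmax(axis=1)  # 0-based index of smallest failing rank
    counts_others = np.where(any_fail, first_fail, t_prime).astype(np.int64)
    return ConservationResult(region, t_prime, counts_others, include_pivot)


def conservation_via_mems(
    mems: Sequence[MemInterval],
    region: QueryRegion,
    t_prime: int,
    include_pivot: bool = True,
    k_min: int | None = None,
) -> ConservationResult:
    """Conservation by containment in order-MEM tracks (the MEM-flavor
    index): the count is the largest rank whose track contains the k-mer."""
    _check_k_bounds(region, None, k_min)
    i, k = region.i, region.k
    last_start = region.j - k
    contained = np.zeros((region.n_starts, t_prime), dtype=bool)
    for m in mems:
        if m.chrom != region.chrom:
            continue
        lo = max(m.start, i)
        hi = min(m.end - k, last_start) + 1
        if lo < hi:
            contained[lo - i : hi - i, m.annotation - 1] = True
    # largest contained rank; 0 when no track contains the k-mer
    ranks = np.arange(1, t_prime + 1)
    counts_others = np.max(np.where(contained, ranks, 0), axis=1).astype(np.int64)
    return ConservationResult(region, t_prime, counts_others, include_pivot)


def quantile_conservation(
    records: Sequence[OverlapRecord],
    region: QueryRegion,
    retained_ranks: Sequence[int],
    rank_labels: Sequence[str] | None = None,
    t_prime: int | None = None,
) -> ConservationResult:
    """Conservation at quantile resolution over a subsampled index.

    Per start, the result is the largest retained rank whose track does
    not fail (the k-mer is contained at that order), reported with its
    quantile label; when even the smallest retained rank fails the k-mer
    is conserved below the lowest quantile and the count floor is 0.
    """
    ranks = sorted(retained_ranks)
    if not ranks:
        raise ValueError("retained_ranks must be non-empty")
    if rank_labels is None:
        rank_labels = [str(r) for r in ranks]
    labels_by_rank = dict(zip(sorted(retained_ranks), rank_labels))
    track_of = {r: idx for idx, r in enumerate(ranks)}
    failing = _mark_absent(records, region, len(ranks), track_of)
    rank_arr = np.array(ranks)
    passing = ~failing
    certified = np.max(np.where(passing, rank_arr, 0), axis=1).astype(np.int64)
    below = "<" + labels_by_rank[ranks[0]]
    labels = tuple(
        labels_by_rank[int(c)] if c > 0 else below for c in certified
    )
    return ConservationResult(
        region,
        t_prime if t_prime is not None else max(ranks),
        certified,
        include_pivot=False,
        labels=labels,
    )
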