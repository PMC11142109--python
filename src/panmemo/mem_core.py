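"""MEMs from matching-statistics peaks, and the overlap records the index stores.

A maximal exact match (MEM) is an exact substring match between the pivot
and a target genome that can be extended in neither direction.  MEMs map
one-to-one to *peaks* of the sawtooth MS vector: position ``j`` (0-based)
is a peak iff ``ms[j] >= ms[j+1]`` or ``j`` is the last position, and
``ms[j] > 0``.  The peak at ``j`` with value ``ell`` yields the half-open
pivot interval ``[j + 1 - ell, j + 1)``.

What the index actually stores is the *overlap* between each pair of
consecutive MEMs: the record ``(start_of_later, end_of_earlier)``.  A k-mer
that strictly spans such a record — overhang on both sides — is contained
in neither MEM of the pair, hence absent from the target genome.  Three
encodings fall out naturally and are all kept:

* adjoining MEMs give a zero-length record (``start == end``);
* non-touching consecutive MEMs (possible after an ambiguous residue) give
  an inverted record (``start > end``) which every k-mer spanning the gap
  straddles, for any k;
* sentinel records ``(first_start, 0)`` and ``(pivot_len, last_end)`` make
  k-mers that extend past the first or last MEM test absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .matching_stats import MSVector

__all__ = [
    "MemInterval",
    "OverlapRecord",
    "peaks",
    "mems_from_ms",
    "overlaps_from_mems",
    "filter_overlaps_for_max_k",
    "filter_mems_for_min_k",
]


@dataclass(frozen=True, order=True)
class MemInterval:
    """0-based half-open MEM interval on the pivot, annotated by genome id
    (membership index) or order rank (conservation index)."""

    chrom: str
    start: int
    end: int
    annotation: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"MEM must have positive length: [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class OverlapRecord:
    """Consecutive-MEM overlap: start of the later MEM, end of the earlier.

    ``start == end`` for adjoining MEMs, ``start > end`` for a gap between
    MEMs and for sentinels.
    """

    chrom: str
    start: int
    end: int
    annotation: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError("overlap record offsets must be non-negative")


def peaks(ms: MSVector) -> list[tuple[int, int]]:
    """Positions ``j`` (0-based) where the MS vector peaks, with the match
    length there.  Zero MS values are never peaks: a zero-length MEM is not
    an exact match."""
    vals = ms.values
    m = vals.size
    out = []
    for j in range(m):
        if vals[j] > 0 and (j == m - 1 or vals[j] >= vals[j + 1]):
            out.append((j, int(vals[j])))
    return out


def mems_from_ms(ms: MSVector, annotation: int, chrom: str | None = None) -> list[MemInterval]:
    """MEM intervals from MS peaks: peak ``(j, ell)`` -> ``[j+1-ell, j+1)``.

    Output is sorted with strictly increasing starts and ends, so no
    interval contains another.
    """
    chrom = ms.pivot_sequence_name if chrom is None else chrom
    return [
        MemInterval(chrom, j + 1 - ell, j + 1, annotation) for j, ell in peaks(ms)
    ]


def overlaps_from_mems(
    mems: Sequence[MemInterval], pivot_len: int, annotation: int, chrom: str = ""
) -> list[OverlapRecord]:
    """Overlap records for a sorted, non-containing MEM track, with leading
    and trailing sentinels.

    An empty track collapses to the single record ``(pivot_len, 0)``, which
    every k-mer straddles: nothing matches, so every k-mer tests absent.
    """
    if not mems:
        return [OverlapRecord(chrom, pivot_len, 0, annotation)]
    for a, b in zip(mems, mems[1:]):
        if not (a.start < b.start and a.end < b.end):
            raise ValueError("MEM track must be sorted with strictly increasing starts and ends")
    chrom = mems[0].chrom
    records = [OverlapRecord(chrom, mems[0].start, 0, annotation)]
    for a, b in zip(mems, mems[1:]):
        records.append(OverlapRecord(chrom, b.start, a.end, annotation))
    records.append(OverlapRecord(chrom, pivot_len, mems[-1].end, annotation))
    return records


def filter_overlaps_for_max_k(
    records: Iterable[OverlapRecord], k_max: int
) -> list[OverlapRecord]:
    """Drop overlap records no k-mer of length <= k_max can straddle.

    A k-mer straddles a record of length ``L = end - start`` only when
    ``k >= L + 2`` (one overhang base each side), so records with
    ``L > k_max - 2`` are dead weight for queries restricted to
    ``k <= k_max``.  Zero-length, inverted (gap) and sentinel records all
    have ``L <= 0`` and are always kept.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    return [r for r in records if r.end - r.start <= k_max - 2]


def filter_mems_for_min_k(mems: Iterable[MemInterval], k_min: int) -> list[MemInterval]:
    """Drop MEMs shorter than k_min: they cannot contain any k-mer with
    ``k >= k_min``, so containment queries restricted to such k are
    unchanged."""
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    return [m for m in mems if m.length >= k_min]
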