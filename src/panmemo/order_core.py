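"""Order statistics over matching-statistics vectors.

Stacking the MS vectors of the pivot against each of the ``t' = t - 1``
other genomes gives a matrix ``L`` with one row per genome.  Sorting each
column of ``L`` in descending order produces the order-MS matrix ``O``:
row ``r`` of ``O`` no longer tracks a single genome but the r-th largest
match length at every pivot position.  Crucially the sort preserves the
sawtooth property row-wise, so the peak-to-MEM mapping applies unchanged
and yields *order-MEMs*: a k-mer contained in an order-r MEM occurs in at
least r of the non-pivot genomes.

Quantile sampling is the lossy variant: keep only the order rows at the
requested quantiles of ``t'`` (for deciles of 89 haplotypes these are
ranks 9, 18, 27, ..., 89) and answer conservation to the nearest lower
retained rank.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .matching_stats import MSVector
from .mem_core import MemInterval, OverlapRecord, mems_from_ms, overlaps_from_mems

__all__ = [
    "order_ms",
    "order_mems",
    "order_overlaps",
    "quantile_rows",
    "quantile_rank_map",
    "subsample_orders",
    "DECILES",
]

DECILES = tuple(Fraction(i, 10) for i in range(1, 11))


def order_ms(L: Sequence[MSVector] | np.ndarray) -> np.ndarray:
    """Column-wise descending sort of the MS matrix.

    Accepts a list of MSVector rows (all the same length) or a 2-D array;
    returns the order-MS matrix as an int array with row 0 holding the
    largest value per column.  Each column of the output is a permutation
    of the corresponding input column, and every output row keeps the
    sawtooth property.
    """
    if isinstance(L, np.ndarray):
        mat = np.asarray(L, dtype=np.int64)
        if mat.ndim != 2 or mat.size == 0:
            raise ValueError("MS matrix must be non-empty and 2-D")
    else:
        rows = list(L)
        if not rows:
            raise ValueError("MS matrix must have at least one row")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged MS matrix: row lengths {sorted(lengths)}")
        mat = np.stack([r.values for r in rows])
    return -np.sort(-mat, axis=0)


def order_mems(O: np.ndarray, chrom: str) -> list[MemInterval]:
    """Order-MEMs: the peak-to-MEM mapping applied to every row of the
    order-MS matrix, annotated with the 1-based order rank."""
    out: list[MemInterval] = []
    for r, row in enumerate(O, start=1):
        out.extend(mems_from_ms(MSVector(chrom, row), annotation=r))
    return out


def order_overlaps(
    order_mem_list: Iterable[MemInterval], pivot_len: int, chrom: str, t_prime: int
) -> list[OverlapRecord]:
    """Overlap records per order track, each with its own sentinels.

    Every rank in ``1..t_prime`` gets a track even if it holds no MEMs (an
    empty track contributes the all-absent record ``(pivot_len, 0)``).
    """
    by_rank: dict[int, list[MemInterval]] = {r: [] for r in range(1, t_prime + 1)}
    for mem in order_mem_list:
        by_rank[mem.annotation].append(mem)
    records: list[OverlapRecord] = []
    for rank in range(1, t_prime + 1):
        track = sorted(by_rank[rank])
        records.extend(overlaps_from_mems(track, pivot_len, rank, chrom=chrom))
    return records


def quantile_rows(t_prime: int, quantiles: Iterable[float | Fraction]) -> list[int]:
    """Order ranks retained when sampling the given quantiles of ``t_prime``
    samples: for each quantile q, the smallest integer x with
    ``x >= q * t_prime`` — the rank whose order-MEMs certify presence in at
    least q of the samples.

    Quantiles are taken over (0, 1].  Exact rational arithmetic avoids
    binary-float ceiling artefacts (e.g. 0.1 * 90 slightly exceeding 9).
    """
    if t_prime < 1:
        raise ValueError("t_prime must be >= 1")
    ranks = set()
    for q in quantiles:
        frac = q if isinstance(q, Fraction) else Fraction(q).limit_denominator(10**6)
        if not (0 < frac <= 1):
            raise ValueError(f"quantile must lie in (0, 1]: {q}")
        target = frac * t_prime
        x = int(target) if target.denominator == 1 else int(target) + 1
        ranks.add(x)
    return sorted(ranks)


def quantile_rank_map(
    t_prime: int, quantiles: Iterable[float | Fraction]
) -> dict[int, Fraction]:
    """Map each retained rank to the largest quantile it certifies (several
    quantiles can collapse onto one rank when t_prime is small)."""
    out: dict[int, Fraction] = {}
    for q in quantiles:
        frac = q if isinstance(q, Fraction) else Fraction(q).limit_denominator(10**6)
        (rank,) = quantile_rows(t_prime, [frac])
        if rank not in out or frac > out[rank]:
            out[rank] = frac
    return out


def subsample_orders(
    records: Iterable[OverlapRecord], retained_ranks: Iterable[int]
) -> list[OverlapRecord]:
    """Keep only the records of the retained order tracks; each retained
    track passes through complete and unchanged."""
    keep = set(retained_ranks)
    return [r for r in records if r.annotation in keep]
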