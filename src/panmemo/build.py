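"""Index construction pipeline: pangenome in, sorted records + metadata out.

For each non-pivot genome a target text (both strands, separator-guarded)
is built once; every pivot sequence is then streamed against it to obtain
matching statistics.  Membership flavors derive per-genome MEM or overlap
tracks; conservation flavors stack the MS vectors per pivot sequence,
column-sort them into the order-MS matrix and derive order tracks, with
optional quantile subsampling and k-range filtering before the records are
sorted for columnar storage.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .index_store import DEFAULT_BLOCK_BYTES, IndexMetadata
from .matching_stats import MSVector, SuffixAutomaton, compute_ms_automaton
from .mem_core import (
    MemInterval,
    filter_mems_for_min_k,
    filter_overlaps_for_max_k,
    mems_from_ms,
    overlaps_from_mems,
)
from .order_core import (
    order_mems,
    order_ms,
    order_overlaps,
    quantile_rank_map,
    subsample_orders,
)
from .seq_io import GenomeSequence, build_target_text

__all__ = ["compute_ms_table", "build_index_records"]

_RECORD_SORT = lambda r: (r.chrom, r.start, r.end, r.annotation)


def compute_ms_table(
    pivot: GenomeSequence, others: Sequence[GenomeSequence]
) -> dict[str, list[MSVector]]:
    """Matching statistics of every pivot sequence against every non-pivot
    genome: ``{pivot_sequence_name: [MSVector per genome, in roster order]}``."""
    table: dict[str, list[MSVector]] = {name: [] for name in pivot.sequence_names}
    for genome in others:
        automaton = SuffixAutomaton(build_target_text(genome).tokens)
        for seq_name, seq in pivot.sequences:
            table[seq_name].append(compute_ms_automaton(seq, automaton, seq_name))
    return table


def build_index_records(
    pivot: GenomeSequence,
    others: Sequence[GenomeSequence],
    flavor: str,
    quantiles: Iterable[float | Fraction] | None = None,
    k_max: int | None = None,
    k_min: int | None = None,
    row_block_target_bytes: int = DEFAULT_BLOCK_BYTES,
    ms_table: dict[str, list[MSVector]] | None = None,
) -> tuple[list, IndexMetadata]:
    """Build the sorted record list and metadata for one index flavor.

    ``k_max`` applies to overlap flavors (drops records no permitted k-mer
    can straddle); ``k_min`` to MEM flavors (drops MEMs too short to
    contain a permitted k-mer).  ``quantiles`` subsamples conservation
    order tracks.  A precomputed MS table may be passed to build several
    flavors from one set of comparisons.
    """
    t_prime = len(others)
    if t_prime < 1:
        raise ValueError("need at least one non-pivot genome")
    if ms_table is None:
        ms_table = compute_ms_table(pivot, others)

    store_overlaps = flavor.endswith("-overlap")
    if k_max is not None and not store_overlaps:
        raise ValueError("k_max filtering applies to overlap flavors")
    if k_min is not None and store_overlaps:
        raise ValueError("k_min filtering applies to MEM flavors")

    records: list = []
    retained: tuple[int, ...] | str = "all"
    labels: tuple[str, ...] | None = None

    if flavor.startswith("membership"):
        for seq_name, seq in pivot.sequences:
            for g in range(t_prime):
                mems = mems_from_ms(ms_table[seq_name][g], annotation=g)
                if store_overlaps:
                    recs = overlaps_from_mems(mems, len(seq), g, chrom=seq_name)
                    if k_max is not None:
                        recs = filter_overlaps_for_max_k(recs, k_max)
                    records.extend(recs)
                else:
                    if k_min is not None:
                        mems = filter_mems_for_min_k(mems, k_min)
                    records.extend(mems)
    elif flavor.startswith("conservation"):
        rank_map = None
        if quantiles is not None:
            rank_map = quantile_rank_map(t_prime, quantiles)
            retained = tuple(sorted(rank_map))
            labels = tuple(
                f"{float(rank_map[r]) * 100:g}%" for r in sorted(rank_map)
            )
        for seq_name, seq in pivot.sequences:
            O = order_ms(ms_table[seq_name])
            omems = order_mems(O, chrom=seq_name)
            if store_overlaps:
                recs = order_overlaps(omems, len(seq), seq_name, t_prime)
                if retained != "all":
                    recs = subsample_orders(recs, retained)
                if k_max is not None:
                    recs = filter_overlaps_for_max_k(recs, k_max)
                records.extend(recs)
            else:
                if retained != "all":
                    omems = [m for m in omems if m.annotation in retained]
                if k_min is not None:
                    omems = filter_mems_for_min_k(omems, k_min)
                records.extend(omems)
    else:
        raise ValueError(f"unknown flavor {flavor!r}")

    records.sort(key=_RECORD_SORT)
    metadata = IndexMetadata(
        flavor=flavor,
        pivot_name=pivot.name,
        genome_names=tuple(g.name for g in others),
        pivot_sequences=tuple((n, len(s)) for n, s in pivot.sequences),
        t_prime=t_prime,
        retained_orders=retained,
        retained_quantiles=labels,
        k_max=k_max,
        k_min=k_min,
        row_block_target_bytes=row_block_target_bytes,
    )
    return records, metadata
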