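"""Columnar on-disk index: Parquet with ZSTD-compressed columns.

One index file holds every interval record — MEMs or consecutive-MEM
overlaps, annotated by genome id or order rank — as four columns
(dictionary-encoded chromosome, unsigned start, unsigned end, unsigned
annotation), sorted by (chrom, start, end, annotation) so that redundant
coordinate values sit close together and compress well.  Index-level
metadata (pivot identity, genome roster, flavor, retained orders,
permitted k-range, pivot sequence lengths) travels in the Parquet footer's
key-value metadata, so the file is self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pyarrow as pa
import pyarrow.parquet as pq

from .mem_core import MemInterval, OverlapRecord

__all__ = [
    "IndexMetadata",
    "FLAVORS",
    "write_index",
    "read_index",
    "read_region",
    "export_bed",
]

FLAVORS = (
    "membership-overlap",
    "membership-mem",
    "conservation-overlap",
    "conservation-mem",
)

_METADATA_KEY = b"panmemo.index"
_SCHEMA_VERSION = 1

# ~16 bytes per in-memory record value set; desk-scale row blocks default to
# 16 MiB (the format supports much larger blocks for pangenome scale)
_BYTES_PER_ROW = 16
DEFAULT_BLOCK_BYTES = 16 * 2**20


@dataclass(frozen=True)
class IndexMetadata:
    """Self-description of one index file; governs query validity."""

    flavor: str
    pivot_name: str
    genome_names: tuple[str, ...]  # non-pivot genomes, order defines genome id
    pivot_sequences: tuple[tuple[str, int], ...]  # (sequence name, length)
    t_prime: int
    retained_orders: tuple[int, ...] | str = "all"
    retained_quantiles: tuple[str, ...] | None = None  # labels parallel to ranks
    k_max: int | None = None
    k_min: int | None = None
    row_block_target_bytes: int = DEFAULT_BLOCK_BYTES
    schema_version: int = _SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.flavor not in FLAVORS:
            raise ValueError(f"unknown index flavor {self.flavor!r}; expected one of {FLAVORS}")
        object.__setattr__(self, "genome_names", tuple(self.genome_names))
        object.__setattr__(
            self, "pivot_sequences", tuple((n, int(l)) for n, l in self.pivot_sequences)
        )
        if self.retained_orders != "all":
            object.__setattr__(self, "retained_orders", tuple(int(r) for r in self.retained_orders))
        if self.retained_quantiles is not None:
            object.__setattr__(self, "retained_quantiles", tuple(self.retained_quantiles))

    @property
    def stores_overlaps(self) -> bool:
        return self.flavor.endswith("-overlap")

    @property
    def is_conservation(self) -> bool:
        return self.flavor.startswith("conservation")

    def pivot_sequence_length(self, chrom: str) -> int:
        for name, length in self.pivot_sequences:
            if name == chrom:
                return length
        raise KeyError(f"unknown pivot sequence {chrom!r}")

    def valid_annotations(self) -> set[int]:
        if self.is_conservation:
            if self.retained_orders == "all":
                return set(range(1, self.t_prime + 1))
            return set(self.retained_orders)
        return set(range(len(self.genome_names)))

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "IndexMetadata":
        d = json.loads(payload)
        d["genome_names"] = tuple(d["genome_names"])
        d["pivot_sequences"] = tuple((n, l) for n, l in d["pivot_sequences"])
        if d["retained_orders"] != "all":
            d["retained_orders"] = tuple(d["retained_orders"])
        if d.get("retained_quantiles") is not None:
            d["retained_quantiles"] = tuple(d["retained_quantiles"])
        return cls(**d)


_SORT_KEY = lambda r: (r.chrom, r.start, r.end, r.annotation)


def _records_to_table(records: Sequence, metadata: IndexMetadata) -> pa.Table:
    valid = metadata.valid_annotations()
    for r in records:
        if r.annotation not in valid:
            raise ValueError(
                f"record annotation {r.annotation} outside metadata roster for flavor {metadata.flavor}"
            )
    keys = [_SORT_KEY(r) for r in records]
    if any(a > b for a, b in zip(keys, keys[1:])):
        raise ValueError("records must be sorted by (chrom, start, end, annotation)")
    schema = pa.schema(
        [
            pa.field("chrom", pa.dictionary(pa.int32(), pa.string())),
            pa.field("start", pa.uint32()),
            pa.field("end", pa.uint32()),
            pa.field("annotation", pa.uint32()),
        ],
        metadata={_METADATA_KEY: metadata.to_json().encode()},
    )
    return pa.table(
        {
            "chrom": pa.array([r.chrom for r in records]).dictionary_encode(),
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "annotation": [r.annotation for r in records],
        },
        schema=schema,
    )


def write_index(records: Sequence, metadata: IndexMetadata, path: str | Path) -> None:
    """Write sorted records plus metadata to a ZSTD-compressed Parquet file.

    Raises if the records are unsorted or carry annotations outside the
    metadata's genome/order roster.
    """
    table = _records_to_table(records, metadata)
    rows_per_block = max(1, metadata.row_block_target_bytes // _BYTES_PER_ROW)
    pq.write_table(
        table,
        path,
        compression="zstd",
        row_group_size=rows_per_block,
        use_dictionary=["chrom"],
        write_statistics=True,
    )


def _table_to_records(table: pa.Table, metadata: IndexMetadata) -> list:
    cls = OverlapRecord if metadata.stores_overlaps else MemInterval
    chroms = table.column("chrom").to_pylist()
    starts = table.column("start").to_pylist()
    ends = table.column("end").to_pylist()
    annos = table.column("annotation").to_pylist()
    return [cls(c, s, e, a) for c, s, e, a in zip(chroms, starts, ends, annos)]


def read_metadata(path: str | Path) -> IndexMetadata:
    meta = pq.read_schema(path).metadata or {}
    if _METADATA_KEY not in meta:
        raise ValueError(f"{path}: not a panmemo index (missing footer metadata)")
    return IndexMetadata.from_json(meta[_METADATA_KEY].decode())


def read_index(path: str | Path) -> tuple[list, IndexMetadata]:
    """Read the full record list and metadata back from an index file."""
    metadata = read_metadata(path)
    table = pq.read_table(path)
    return _table_to_records(table, metadata), metadata


def read_region(path: str | Path, chrom: str, i: int, j: int) -> tuple[list, IndexMetadata]:
    """Fetch exactly the records that can influence a k-mer query inside
    ``[i, j)`` of one pivot sequence.

    For overlap flavors these are records with ``start > i and end < j``
    (a record marks absent only starts in ``[end - k + 1, start)``), plus
    every sentinel record of the chromosome so that per-track boundary
    handling survives the subset.  For MEM flavors they are the intervals
    overlapping the region.  Queries over the fetched subset equal queries
    over a full scan.
    """
    if not (0 <= i < j):
        raise ValueError(f"invalid region [{i}, {j})")
    metadata = read_metadata(path)
    pivot_len = metadata.pivot_sequence_length(chrom)  # KeyError -> unknown chrom
    table = pq.read_table(path)
    records = _table_to_records(table, metadata)
    if metadata.stores_overlaps:
        kept = [
            r
            for r in records
            if r.chrom == chrom
            and ((r.start > i and r.end < j) or r.end == 0 or r.start == pivot_len)
        ]
    else:
        kept = [r for r in records if r.chrom == chrom and r.start < j and r.end > i]
    return kept, metadata


def export_bed(path: str | Path, out_path: str | Path) -> None:
    """Export an index as 4-column BED (chrom, start, end, annotation).

    Overlap tracks may contain inverted records (start > end: MEM gaps and
    sentinels); these are written as-is and flagged in a header comment as
    a nonstandard BED dialect.
    """
    records, metadata = read_index(path)
    has_inverted = any(r.end < r.start for r in records)
    with open(out_path, "wt") as fh:
        fh.write(f"# panmemo {metadata.flavor} index export; pivot={metadata.pivot_name}\n")
        if has_inverted:
            fh.write(
                "# NONSTANDARD BED: records with start > end encode MEM gaps and sentinels\n"
            )
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.annotation}\n")
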