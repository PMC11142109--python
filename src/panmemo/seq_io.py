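"""FASTA input and the searchable target text.

Coordinate conventions used throughout the package are fixed here: all
intervals are 0-based half-open ``[start, end)``.  A genome is an ordered
collection of named DNA sequences; the *target text* built from a genome is
the concatenation, per sequence, of the forward strand and its reverse
complement, each followed by a separator.  Separators and non-ACGT residues
are encoded as per-occurrence unique tokens so that no match can cross a
sequence boundary and ambiguous residues (N, IUPAC codes) never match
anything, including themselves.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "TargetText",
    "load_fasta",
    "build_target_text",
    "revcomp",
    "SEPARATOR",
]

SEPARATOR = "$"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")
_ACGT_SET = frozenset("ACGT")

# token codes for the matchable alphabet; everything else gets a unique
# negative token and therefore matches nothing
_BASE_TOKEN = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string, uppercased; non-ACGT characters
    map to N."""
    rc = seq.translate(_COMPLEMENT)[::-1]
    if _ACGT_SET.issuperset(rc):
        return rc
    return "".join(c if c in _ACGT_SET else "N" for c in rc)


@dataclass(frozen=True)
class GenomeSequence:
    """One genome: a name plus an ordered list of (sequence_name, residues).

    Residues are uppercased on construction; sequence names must be unique
    within the genome.
    """

    name: str
    sequences: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        norm = tuple((n, s.upper()) for n, s in self.sequences)
        object.__setattr__(self, "sequences", norm)
        names = [n for n, _ in norm]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"duplicate sequence name(s) in genome {self.name!r}: {dup}"
            )

    @property
    def sequence_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.sequences)

    def sequence(self, name: str) -> str:
        for n, s in self.sequences:
            if n == name:
                return s
        raise KeyError(f"no sequence {name!r} in genome {self.name!r}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.sequences)


@dataclass(frozen=True)
class TargetText:
    """Searchable text of one genome: both strands, separator-delimited.

    ``text`` is the human-readable form (separator rendered as ``$``,
    non-ACGT residues kept verbatim); ``tokens`` is the matchable form in
    which A/C/G/T map to 0..3 and every separator or ambiguous residue is a
    distinct negative integer, so it can never take part in a match.
    """

    genome_name: str
    text: str
    tokens: tuple[int, ...]


def pattern_tokens(pattern: str, *, start_token: int = -1_000_000_000) -> list[int]:
    """Tokenize a query pattern; non-ACGT residues become unique unmatchable
    tokens drawn from a range disjoint from any target text's tokens."""
    toks: list[int] = []
    nxt = start_token
    for ch in pattern.upper():
        code = _BASE_TOKEN.get(ch)
        if code is None:
            toks.append(nxt)
            nxt -= 1
        else:
            toks.append(code)
    return toks


def build_target_text(genome: GenomeSequence) -> TargetText:
    """Concatenate ``S + $ + revcomp(S) + $`` for every sequence of a genome.

    The forward block of each sequence precedes its reverse-complement
    block.  ``len(text) == 2 * total_residues + 2 * n_sequences``.
    """
    parts: list[str] = []
    tokens: list[int] = []
    unmatch = -1  # unique negative token per separator / ambiguous residue

    def emit(s: str) -> None:
        nonlocal unmatch
        for ch in s:
            code = _BASE_TOKEN.get(ch)
            if code is None:
                tokens.append(unmatch)
                unmatch -= 1
            else:
                tokens.append(code)
        parts.append(s)

    for _, seq in genome.sequences:
        emit(seq)
        tokens.append(unmatch)
        unmatch -= 1
        parts.append(SEPARATOR)
        emit(revcomp(seq))
        tokens.append(unmatch)
        unmatch -= 1
        parts.append(SEPARATOR)

    return TargetText(genome.name, "".join(parts), tuple(tokens))


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_fasta(path: str | Path, name: str | None = None) -> GenomeSequence:
    """Load a (possibly gzip-compressed) multi-record FASTA as one genome.

    Record order is preserved and residues are uppercased.  Raises
    ``ValueError`` for an empty file, a file whose first non-blank line is
    not a FASTA header (naming the offending line), or duplicate record
    names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno} is not a FASTA header: {line.strip()!r}"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    with _open_maybe_gzip(path) as fh:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if name is None:
        name = path.name
        for suffix in (".gz", ".fa", ".fasta", ".fna"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
    return GenomeSequence(name=name, sequences=tuple(records))


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    """Write a genome as plain uncompressed FASTA."""
    with open(path, "wt") as fh:
        for seq_name, seq in genome.sequences:
            fh.write(f">{seq_name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if not seq:
                fh.write("\n")
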