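"""Synthetic pangenome generator.

Emulates a star-phylogeny pangenome: a uniformly random pivot genome plus
``t - 1`` derived genomes, each obtained from the pivot independently by
point substitutions (to a different base) and short insertions/deletions
at configurable per-base rates.  Deterministic under a seed, so every
pipeline stage is testable without downloads.  No demography, structural
variation or sequencing error is modelled — divergence control is all the
downstream correctness tests need.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .seq_io import GenomeSequence, write_fasta

__all__ = ["SimulationConfig", "simulate_pangenome", "write_pangenome"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    pivot_length: int = 5000  # per sequence, bp
    n_sequences: int = 1
    t: int = 4  # total genomes incl. pivot
    snp_rate: float = 0.01
    indel_rate: float = 0.001
    max_indel_len: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for rate_name in ("snp_rate", "indel_rate"):
            rate = getattr(self, rate_name)
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{rate_name} must lie in [0, 1]: {rate}")
        if self.t < 1 or self.pivot_length < 0 or self.n_sequences < 1:
            raise ValueError("t and n_sequences must be >= 1, pivot_length >= 0")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")


def _mutate(seq: str, rng: np.random.Generator, cfg: SimulationConfig) -> tuple[str, list]:
    """Apply SNPs then indels to one sequence; returns the derived sequence
    and a mutation log (kind, pivot position, detail)."""
    arr = np.array(list(seq))
    log: list[dict] = []
    if len(arr) and cfg.snp_rate > 0:
        hit = rng.random(len(arr)) < cfg.snp_rate
        for pos in np.flatnonzero(hit):
            old = arr[pos]
            choices = _BASES[_BASES != old]
            new = rng.choice(choices)
            arr[pos] = new
            log.append({"kind": "snp", "pos": int(pos), "from": str(old), "to": str(new)})
    out: list[str] = []
    pos = 0
    n = len(arr)
    while pos < n:
        if cfg.indel_rate > 0 and rng.random() < cfg.indel_rate:
            length = int(rng.integers(1, cfg.max_indel_len + 1))
            if rng.random() < 0.5:
                ins = "".join(rng.choice(_BASES, size=length))
                out.append(ins)
                out.append(str(arr[pos]))
                log.append({"kind": "ins", "pos": int(pos), "seq": ins})
                pos += 1
            else:
                log.append({"kind": "del", "pos": int(pos), "len": length})
                pos += length
        else:
            out.append(str(arr[pos]))
            pos += 1
    return "".join(out), log


def simulate_pangenome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GenomeSequence], dict]:
    """Generate (pivot, derived genomes, mutation manifest) in memory.

    The pivot is uniform over ACGT; each derived genome applies independent
    mutations to every pivot sequence.  Two runs with the same config are
    identical.
    """
    rng = np.random.default_rng(config.seed)
    pivot_seqs = []
    for s in range(config.n_sequences):
        residues = "".join(rng.choice(_BASES, size=config.pivot_length))
        pivot_seqs.append((f"piv_seq{s}", residues))
    pivot = GenomeSequence("pivot", tuple(pivot_seqs))
    manifest: dict = {"config": asdict(config), "genomes": {}}
    derived = []
    for g in range(1, config.t):
        seqs = []
        glog: dict[str, list] = {}
        for seq_name, seq in pivot.sequences:
            mutated, log = _mutate(seq, rng, config)
            seqs.append((seq_name, mutated))
            glog[seq_name] = log
        name = f"genome{g}"
        derived.append(GenomeSequence(name, tuple(seqs)))
        manifest["genomes"][name] = glog
    return pivot, derived, manifest


def write_pangenome(config: SimulationConfig, out_dir: str | Path) -> list[Path]:
    """Simulate and write one FASTA per genome plus a JSON mutation
    manifest; returns the FASTA paths (pivot first)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pivot, derived, manifest = simulate_pangenome(config)
    paths = []
    for genome in [pivot, *derived]:
        p = out_dir / f"{genome.name}.fa"
        write_fasta(genome, p)
        paths.append(p)
    with open(out_dir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths
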