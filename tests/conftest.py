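"""Shared fixtures: the hand-checked three-genome example and small
simulated pangenomes."""

from __future__ import annotations

import pytest

from panmemo import (
    GenomeSequence,
    SimulationConfig,
    build_target_text,
    compute_ms,
    simulate_pangenome,
)
from panmemo.build import compute_ms_table


@pytest.fixture(scope="session")
def worked_example():
    """Pivot ACGTT against ACGTA and CGTTG: every intermediate value of
    this example was independently recomputed with the brute-force oracles
    before being frozen into the tests that use it."""
    pivot = GenomeSequence("pivot", (("piv", "ACGTT"),))
    g2 = GenomeSequence("G2", (("s", "ACGTA"),))
    g3 = GenomeSequence("G3", (("s", "CGTTG"),))
    ms = compute_ms_table(pivot, [g2, g3])
    return {"pivot": pivot, "others": [g2, g3], "ms": ms["piv"]}


def make_pangenome(seed: int, **kwargs):
    defaults = dict(pivot_length=800, n_sequences=1, t=4, snp_rate=0.01,
                    indel_rate=0.001, seed=seed)
    defaults.update(kwargs)
    cfg = SimulationConfig(**defaults)
    pivot, others, _ = simulate_pangenome(cfg)
    return pivot, others


@pytest.fixture(scope="session")
def small_pangenome():
    """One modest simulated pangenome reused by store/query tests."""
    pivot, others = make_pangenome(seed=7, pivot_length=1500, t=5,
                                   snp_rate=0.02, indel_rate=0.002)
    return pivot, others, compute_ms_table(pivot, others)
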