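"""Query semantics: worked examples, equivalence of the two index routes
against the canonical-k-mer oracle, and the conservation identities."""

import numpy as np
import pytest

from panmemo import (
    QueryRegion,
    build_index_records,
    conservation,
    conservation_via_mems,
    membership,
    membership_via_mems,
    oracle_conservation,
    oracle_membership,
    quantile_conservation,
)
from panmemo.order_core import DECILES, quantile_rank_map, quantile_rows, subsample_orders
from conftest import make_pangenome


@pytest.fixture(scope="module")
def worked_records(worked_example):
    pivot, others = worked_example["pivot"], worked_example["others"]
    mem_over, mem_meta = build_index_records(pivot, others, "membership-overlap")
    mem_mems, _ = build_index_records(pivot, others, "membership-mem")
    con_over, con_meta = build_index_records(pivot, others, "conservation-overlap")
    return {
        "pivot": pivot,
        "others": others,
        "mem_over": mem_over,
        "mem_mems": mem_mems,
        "con_over": con_over,
        "meta": mem_meta,
        "con_meta": con_meta,
    }


def test_membership_worked_example_k2(worked_records):
    region = QueryRegion("piv", 0, 5, 2)
    res = membership(worked_records["mem_over"], region, ("G2", "G3"))
    # G2=ACGTA lacks only "TT" among the pivot's 2-mers
    assert list(res.matrix[:, 0]) == [True, True, True, False]


def test_membership_worked_example_k4(worked_records):
    region = QueryRegion("piv", 0, 5, 4)
    res = membership(worked_records["mem_over"], region, ("G2", "G3"))
    assert list(res.matrix[:, 0]) == [True, False]  # CGTT absent from G2


def test_membership_via_mems_matches_overlap_route(worked_records):
    for k in (1, 2, 3, 4, 5):
        region = QueryRegion("piv", 0, 5, k)
        a = membership(worked_records["mem_over"], region, ("G2", "G3"))
        b = membership_via_mems(worked_records["mem_mems"], region, ("G2", "G3"))
        assert np.array_equal(a.matrix, b.matrix)


def test_conservation_worked_example(worked_records):
    region = QueryRegion("piv", 0, 5, 3)
    res = conservation(worked_records["con_over"], region, t_prime=2)
    assert list(res.counts) == [3, 3, 2]
    assert list(res.counts_others) == [2, 2, 1]
    oc = oracle_conservation(worked_records["pivot"], worked_records["others"], region)
    assert np.array_equal(res.counts, oc.counts)


def test_conservation_whole_pivot_kmer(worked_records):
    res = conservation(worked_records["con_over"], QueryRegion("piv", 0, 5, 5), 2)
    assert list(res.counts) == [1]  # ACGTT occurs only in the pivot
    assert list(res.counts_others) == [0]


def test_membership_no_mems_all_absent():
    region = QueryRegion("c", 0, 5, 2)
    res = membership_via_mems([], region, ("g",))
    assert not res.matrix.any()


def test_query_k_bounds_enforced(worked_records):
    region = QueryRegion("piv", 0, 5, 4)
    with pytest.raises(ValueError, match="k_max"):
        membership(worked_records["mem_over"], region, ("G2", "G3"), k_max=3)
    with pytest.raises(ValueError, match="k_min"):
        membership_via_mems(worked_records["mem_mems"], region, ("G2", "G3"), k_min=5)
    with pytest.raises(ValueError, match="shorter"):
        QueryRegion("piv", 0, 3, 4)


@pytest.mark.parametrize("seed,t,snp", [(21, 2, 0.02), (22, 5, 0.01), (23, 8, 0.005)])
def test_three_way_equivalence_random(seed, t, snp):
    """Overlap route == MEM-containment route == canonical-k-mer oracle on
    simulated pangenomes, for a spread of k."""
    pivot, others = make_pangenome(seed=seed, pivot_length=700, t=t, snp_rate=snp)
    chrom, pseq = pivot.sequences[0]
    mem_over, meta = build_index_records(pivot, others, "membership-overlap")
    mem_mems, _ = build_index_records(pivot, others, "membership-mem")
    con_over, _ = build_index_records(pivot, others, "conservation-overlap")
    for k in (1, 2, 4, 11, 21, 51):
        region = QueryRegion(chrom, 0, len(pseq), k)
        a = membership(mem_over, region, meta.genome_names)
        b = membership_via_mems(mem_mems, region, meta.genome_names)
        o = oracle_membership(pivot, others, region)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.matrix, o.matrix)
        c = conservation(con_over, region, meta.t_prime)
        oc = oracle_conservation(pivot, others, region)
        assert np.array_equal(c.counts, oc.counts)
        # Definition of conservation as the sum of per-genome membership
        assert np.array_equal(c.counts_others, a.matrix.sum(axis=1))


def test_conservation_via_mems_matches_overlap_route():
    pivot, others = make_pangenome(seed=31, pivot_length=500, t=5, snp_rate=0.02)
    chrom, pseq = pivot.sequences[0]
    con_over, meta = build_index_records(pivot, others, "conservation-overlap")
    con_mems, _ = build_index_records(pivot, others, "conservation-mem")
    for k in (2, 7, 21):
        region = QueryRegion(chrom, 0, len(pseq), k)
        a = conservation(con_over, region, meta.t_prime)
        b = conservation_via_mems(con_mems, region, meta.t_prime)
        assert np.array_equal(a.counts, b.counts)


def test_absence_monotone_in_k():
    """If a k-mer is absent from a genome, every longer k-mer covering its
    span is absent too."""
    pivot, others = make_pangenome(seed=41, pivot_length=400, t=3, snp_rate=0.03)
    chrom, pseq = pivot.sequences[0]
    mem_over, meta = build_index_records(pivot, others, "membership-overlap")
    prev = None
    for k in (3, 5, 9):
        res = membership(mem_over, QueryRegion(chrom, 0, len(pseq), k), meta.genome_names)
        if prev is not None:
            k_prev, mat_prev = prev
            n = res.matrix.shape[0]
            # absence of the k_prev-mer at x implies absence of the k-mer at x
            assert not (res.matrix[:n] & ~mat_prev[:n]).any()
        prev = (k, res.matrix)


def test_early_stopping_equivalence():
    """Scanning order tracks in any sequence and stopping at the first
    decidable rank equals the full argmax."""
    pivot, others = make_pangenome(seed=51, pivot_length=400, t=6, snp_rate=0.02)
    chrom, pseq = pivot.sequences[0]
    con_over, meta = build_index_records(pivot, others, "conservation-overlap")
    t_prime = meta.t_prime
    region = QueryRegion(chrom, 0, len(pseq), 11)
    full = conservation(con_over, region, t_prime)
    from panmemo.mem_core import OverlapRecord

    by_rank = {
        r: [OverlapRecord(rec.chrom, rec.start, rec.end, 1)
            for rec in con_over if rec.annotation == r]
        for r in range(1, t_prime + 1)
    }

    def fails(rank, x):
        res = conservation(by_rank[rank], region, 1, include_pivot=False)
        # single-track probe: count_others == 0 iff that track fails at x
        return res.counts_others[x - region.i] == 0

    rng = np.random.default_rng(0)
    for x in rng.choice(full.starts, size=20, replace=False):
        # monotone failing set => binary search with early stop at every
        # decidable probe reconstructs the count from O(log t') probes
        lo, hi = 0, t_prime  # ranks <= lo pass; ranks > hi fail
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if fails(mid, int(x)):
                hi = mid - 1
            else:
                lo = mid
        assert lo == full.counts_others[int(x) - region.i]


def test_quantile_conservation_floors_full_counts():
    pivot, others = make_pangenome(seed=61, pivot_length=600, t=8, snp_rate=0.01)
    chrom, pseq = pivot.sequences[0]
    con_over, meta = build_index_records(pivot, others, "conservation-overlap")
    t_prime = meta.t_prime
    ranks = quantile_rows(t_prime, DECILES)
    labels = [f"{float(q) * 100:g}%" for _, q in sorted(quantile_rank_map(t_prime, DECILES).items())]
    sub = subsample_orders(con_over, ranks)
    for k in (4, 11, 31):
        region = QueryRegion(chrom, 0, len(pseq), k)
        full = conservation(con_over, region, t_prime)
        quant = quantile_conservation(sub, region, ranks, rank_labels=labels, t_prime=t_prime)
        expected = np.array(
            [max([r for r in ranks if r <= c], default=0) for c in full.counts_others]
        )
        assert np.array_equal(quant.counts_others, expected)
        assert quant.labels is not None and len(quant.labels) == len(expected)


def test_quantile_top_and_below_lowest_labels():
    pivot, others = make_pangenome(seed=62, pivot_length=300, t=4, snp_rate=0.0, indel_rate=0.0)
    chrom, pseq = pivot.sequences[0]
    con_over, meta = build_index_records(pivot, others, "conservation-overlap")
    ranks = quantile_rows(meta.t_prime, DECILES)
    sub = subsample_orders(con_over, ranks)
    region = QueryRegion(chrom, 0, len(pseq), 21)
    quant = quantile_conservation(sub, region, ranks, t_prime=meta.t_prime)
    # zero divergence: everything certified at the top rank
    assert (quant.counts_others == meta.t_prime).all()
    # pivot-only style: a single empty track certifies nothing
    from panmemo.mem_core import OverlapRecord
    empty = [OverlapRecord(chrom, len(pseq), 0, 1)]
    q2 = quantile_conservation(empty, region, [1])
    assert (q2.counts_others == 0).all()
    assert set(q2.labels) == {"<1"}


def test_zero_mutation_pangenome_all_present():
    pivot, others = make_pangenome(seed=71, pivot_length=300, t=5,
                                   snp_rate=0.0, indel_rate=0.0)
    chrom, pseq = pivot.sequences[0]
    mem_over, meta = build_index_records(pivot, others, "membership-overlap")
    con_over, _ = build_index_records(pivot, others, "conservation-overlap")
    for k in (1, 11, 151):
        region = QueryRegion(chrom, 0, len(pseq), k)
        assert membership(mem_over, region, meta.genome_names).matrix.all()
        assert (conservation(con_over, region, meta.t_prime).counts == 5).all()


def test_region_windows_match_whole_sequence_query():
    pivot, others = make_pangenome(seed=81, pivot_length=500, t=4, snp_rate=0.02)
    chrom, pseq = pivot.sequences[0]
    mem_over, meta = build_index_records(pivot, others, "membership-overlap")
    k = 7
    whole = membership(mem_over, QueryRegion(chrom, 0, len(pseq), k), meta.genome_names)
    for i, j in ((0, 50), (123, 321), (400, 500)):
        window = membership(mem_over, QueryRegion(chrom, i, j, k), meta.genome_names)
        assert np.array_equal(window.matrix, whole.matrix[i : j - k + 1])
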