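import numpy as np
import pytest

from oracles import oracle_map_interval, oracle_pair_table
from tfosmap.formats import GenomicInterval, read_chains
from tfosmap.mapper import (
    MapStatus,
    map_interval,
    map_intervals,
    mappable_nucleotide_fraction,
    roundtrip,
)
from tfosmap.reciprocal_map import build_bijective_map
from tfosmap.synthetic import random_chains


class TestWorkedExamples:
    def test_interval_inside_first_block(self, two_block_map):
        el = map_interval(GenomicInterval("chrT", 12, 18), two_block_map)
        assert el.status is MapStatus.MAPPED
        assert (el.target.chrom, el.target.start, el.target.end) == ("chrQ", 52, 58)
        assert el.mapped_bases == 6

    def test_interval_spanning_internal_gap(self, two_block_map):
        el = map_interval(GenomicInterval("chrT", 15, 30), two_block_map)
        assert el.status is MapStatus.MAPPED
        assert (el.target.start, el.target.end) == (55, 70)
        assert el.mapped_bases == 10  # bases 20-25 are unaligned

    def test_interval_off_map_unmapped(self, two_block_map):
        el = map_interval(GenomicInterval("chrT", 41, 49), two_block_map)
        assert el.status is MapStatus.UNMAPPED

    def test_two_chain_span_filtered(self):
        txt = ("chain 1000 chrT 100 + 10 30 chrQ 100 + 0 20 1\n20\n"
               "chain 900 chrT 100 + 40 60 chrQ 100 + 40 60 2\n20\n")
        m = build_bijective_map(read_chains(txt), {"chrT": 100}, {"chrQ": 100})
        el = map_interval(GenomicInterval("chrT", 20, 50), m)
        assert el.status is MapStatus.FILTERED_MULTI_CHAIN
        assert el.chain_ids == {"1", "2"}

    def test_roundtrip_on_worked_example(self, two_block_map):
        assert roundtrip(GenomicInterval("chrT", 12, 18), two_block_map)

    def test_min_frac_threshold(self, two_block_map):
        # [15,30): 10 of 15 bases map (2/3)
        iv = GenomicInterval("chrT", 15, 30)
        assert map_interval(iv, two_block_map, min_frac=0.5).status is MapStatus.MAPPED
        assert map_interval(iv, two_block_map, min_frac=0.8).status is MapStatus.UNMAPPED

    def test_bad_direction_rejected(self, two_block_map):
        with pytest.raises(ValueError, match="direction"):
            map_interval(GenomicInterval("chrT", 12, 18), two_block_map,
                         direction="sideways")


def _random_fixture(seed, n_chains=12):
    rng = np.random.default_rng(seed)
    sizes_a = {"c1": 1200, "c2": 700}
    sizes_b = {"d1": 1000, "d2": 800}
    chains = random_chains(rng, sizes_a, sizes_b, n_chains)
    m = build_bijective_map(chains, sizes_a, sizes_b)
    return rng, sizes_a, chains, m


@pytest.mark.parametrize("seed", range(8))
def test_per_base_oracle_equivalence(seed):
    """map_interval agrees with an exhaustive base dictionary for every
    single-base interval and for random multi-base intervals."""
    rng, sizes_a, chains, m = _random_fixture(seed)
    pairs = oracle_pair_table(chains)
    for chrom, size in sizes_a.items():
        for pos in range(size):
            got = map_interval(GenomicInterval(chrom, pos, pos + 1), m)
            status, target, bases = oracle_map_interval(chrom, pos, pos + 1, pairs)
            assert got.status.value == status, (chrom, pos)
            if status == "MAPPED":
                assert (got.target.chrom, got.target.start, got.target.end) == target
                assert got.mapped_bases == bases
    for _ in range(300):
        chrom = ["c1", "c2"][int(rng.integers(2))]
        start = int(rng.integers(0, sizes_a[chrom] - 1))
        end = start + int(rng.integers(1, min(200, sizes_a[chrom] - start) + 1))
        got = map_interval(GenomicInterval(chrom, start, end), m)
        status, target, bases = oracle_map_interval(chrom, start, end, pairs)
        assert got.status.value == status
        if status == "MAPPED":
            assert (got.target.chrom, got.target.start, got.target.end) == target
            assert got.mapped_bases == bases


@pytest.mark.parametrize("seed", range(4))
def test_roundtrip_identity_universal(seed):
    """Every MAPPED element round-trips, including through
    inverted-orientation blocks."""
    rng, sizes_a, chains, m = _random_fixture(seed)
    n_checked = 0
    for _ in range(400):
        chrom = ["c1", "c2"][int(rng.integers(2))]
        start = int(rng.integers(0, sizes_a[chrom] - 1))
        end = start + int(rng.integers(1, 150))
        end = min(end, sizes_a[chrom])
        iv = GenomicInterval(chrom, start, end)
        if map_interval(iv, m).status is MapStatus.MAPPED:
            assert roundtrip(iv, m)
            n_checked += 1
    assert n_checked > 50


def test_roundtrip_through_inverted_block():
    txt = "chain 900 chrT 100 + 10 30 chrQ 100 - 20 40 2\n20\n"
    m = build_bijective_map(read_chains(txt), {"chrT": 100}, {"chrQ": 100})
    iv = GenomicInterval("chrT", 13, 27)
    el = map_interval(iv, m)
    assert el.status is MapStatus.MAPPED
    assert (el.target.start, el.target.end) == (63, 77)
    assert roundtrip(iv, m)


@pytest.mark.parametrize("seed", range(3))
def test_shrinking_never_creates_multi_chain(seed):
    rng, sizes_a, chains, m = _random_fixture(seed)
    for _ in range(200):
        chrom = ["c1", "c2"][int(rng.integers(2))]
        start = int(rng.integers(0, sizes_a[chrom] - 2))
        end = start + int(rng.integers(2, min(300, sizes_a[chrom] - start) + 1))
        outer = map_interval(GenomicInterval(chrom, start, end), m)
        if outer.status is MapStatus.MAPPED:
            s2 = start + int(rng.integers(0, (end - start) // 2 + 1))
            e2 = end - int(rng.integers(0, (end - s2) // 2 + 1))
            if s2 < e2:
                inner = map_interval(GenomicInterval(chrom, s2, e2), m)
                assert inner.status is not MapStatus.FILTERED_MULTI_CHAIN


class TestMapIntervals:
    def test_empty_input(self, two_block_map):
        out, summary = map_intervals([], two_block_map)
        assert out == [] and sum(summary.values()) == 0

    def test_summary_counts_sum_to_input(self, two_block_map):
        ivs = [GenomicInterval("chrT", s, s + 3) for s in range(0, 90, 9)]
        out, summary = map_intervals(ivs, two_block_map)
        assert len(out) == len(ivs)
        assert sum(summary.values()) == len(ivs)
        assert summary[MapStatus.UNMAPPED] == sum(
            1 for el in out if el.status is MapStatus.UNMAPPED)

    def test_nucleotide_fraction_matches_base_table(self, two_block_map):
        ivs = [GenomicInterval("chrT", 12, 18), GenomicInterval("chrT", 15, 30),
               GenomicInterval("chrT", 60, 70)]
        out, _ = map_intervals(ivs, two_block_map)
        # (6 + 10 + 0) partnered bases over (6 + 15 + 10) total
        assert mappable_nucleotide_fraction(out) == pytest.approx(16 / 31)
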