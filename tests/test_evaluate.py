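"""Evaluation math: optimal k, k-mer completeness/QV, NGA50, duplication,
coverage — each checked against closed forms or brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplokit import simulate as sim
from haplokit.evaluate import (
    KmerStats,
    canonical_kmer_array,
    compute_kmer_stats,
    consensus_qv,
    coverage_fraction,
    duplication_ratio,
    kmer_completeness,
    kmer_counts,
    nga50,
    optimal_k,
)


class TestOptimalK:
    def test_targeted_region_value(self):
        k, k_int = optimal_k(4_548_949, 0.001)
        assert k == 16.04
        assert k_int == 16

    def test_power_of_four_at_even_odds(self):
        # (1-e)/e = 1 at e = 0.5, so k = log4(L) exactly
        assert optimal_k(4**10, 0.5)[0] == 10.00

    def test_human_genome_scale_closed_form(self):
        # high-precision oracle for log4(L*(1-e)/e)
        exp = math.log(3.1e9 * 0.999 / 0.001) / math.log(4)
        assert optimal_k(3_100_000_000, 0.001)[0] == round(exp, 2) == 20.75

    def test_monotone_in_length_and_collision_rate(self):
        ks = [optimal_k(L, 0.001)[0] for L in (10_000, 1_000_000, 10_000_000)]
        assert ks == sorted(ks) and len(set(ks)) == 3
        ke = [optimal_k(1_000_000, e)[0] for e in (0.0001, 0.001, 0.01)]
        assert ke == sorted(ke, reverse=True) and len(set(ke)) == 3

    def test_invalid_collision_rate(self):
        with pytest.raises(ValueError):
            optimal_k(1000, 0.0)


class TestKmerMachinery:
    def test_packed_array_matches_string_counter(self):
        seq = sim.simulate_ancestral(sim.RegionSpec(500, 0.45, 51))
        for k in (5, 16):
            packed = Counter(canonical_kmer_array(seq, k).tolist())
            strings = kmer_counts([seq], k)
            assert sum(packed.values()) == sum(strings.values())
            assert sorted(packed.values()) == sorted(strings.values())

    def test_completeness_identity(self):
        hap = sim.simulate_ancestral(sim.RegionSpec(20_000, 0.41, 52))
        reads = [hap[i : i + 2_000] for i in range(0, 19_000, 500)]
        stats = compute_kmer_stats(reads, [hap], 16)
        assert kmer_completeness(stats) == 1.0
        assert consensus_qv(stats) == 99.0

    def test_completeness_direct_ratio(self):
        s = KmerStats(16, 120, 100, 500, 0, 90)
        assert kmer_completeness(s) == 0.90

    def test_missing_segment_lowers_completeness_proportionally(self):
        # oracle: exact canonical k-mer set arithmetic on small sequences
        hap = sim.simulate_ancestral(sim.RegionSpec(30_000, 0.41, 53))
        reads = [hap[i : i + 2_000] for i in range(0, 29_000, 500)]
        truncated = hap[: 27_000]  # drop a 10% segment
        stats = compute_kmer_stats(reads, [truncated], 16)
        got = kmer_completeness(stats)
        reliable = {km for km, n in kmer_counts(reads, 16).items() if n >= 2}
        asm = set(kmer_counts([truncated], 16))
        exact = len(reliable & asm) / len(reliable)
        assert got == pytest.approx(exact)
        assert got == pytest.approx(0.90, abs=0.01)

    def test_qv_closed_form(self):
        s = KmerStats(16, 1000, 1000, 1000, 10, 990)
        err = 1 - (1 - 10 / 1000) ** (1 / 16)
        assert consensus_qv(s) == pytest.approx(-10 * math.log10(err))
        assert consensus_qv(s) == pytest.approx(32.0, abs=0.1)

    def test_single_substitution_creates_k_novel_kmers(self):
        hap = sim.simulate_ancestral(sim.RegionSpec(100_000, 0.41, 54))
        reads = [hap[i : i + 5_000] for i in range(0, 95_001, 1_000)]
        mutated = list(hap)
        mutated[50_000] = "ACGT"[("ACGT".index(hap[50_000]) + 1) % 4]
        stats = compute_kmer_stats(reads, ["".join(mutated)], 16)
        assert stats.asm_only_kmers == 16

    def test_degraded_assembly_ladder(self):
        # truth > truncated > mutated on completeness; truth hits the QV cap
        hap = sim.simulate_ancestral(sim.RegionSpec(30_000, 0.41, 55))
        reads = [hap[i : i + 2_000] for i in range(0, 29_000, 400)]
        rng = np.random.default_rng(55)
        mutated = list(hap)
        for p in rng.choice(len(hap), 300, replace=False):
            mutated[p] = "ACGT"[("ACGT".index(mutated[p]) + 1) % 4]
        variants = {
            "truth": hap,
            "truncated": hap[: int(0.8 * len(hap))],
            "mutated": "".join(mutated),
        }
        comp = {
            name: kmer_completeness(compute_kmer_stats(reads, [s], 16))
            for name, s in variants.items()
        }
        assert comp["truth"] == 1.0
        assert comp["truth"] > comp["truncated"]
        assert comp["truth"] > comp["mutated"]
        assert consensus_qv(compute_kmer_stats(reads, [hap], 16)) == 99.0
        assert consensus_qv(compute_kmer_stats(reads, [variants["mutated"]], 16)) < 99.0

    def test_zero_reliable_kmers_rejected(self):
        with pytest.raises(ValueError):
            kmer_completeness(KmerStats(16, 0, 0, 10, 0, 0))


from haplokit.variants import AlignmentBlock


def blk(rs, re, qs=None, qe=None):
    return AlignmentBlock(rs, re, qs if qs is not None else rs, qe if qe is not None else re)


class TestNga50:
    def test_single_full_block(self):
        assert nga50([blk(0, 100)], 100) == (100, 1)

    def test_simple_cumulative(self):
        blocks = [blk(0, 60), blk(60, 90), blk(90, 100)]
        assert nga50(blocks, 100) == (60, 1)

    def test_cumulative_crosses_at_second(self):
        blocks = [blk(0, 40), blk(40, 70), blk(70, 90), blk(90, 100)]
        assert nga50(blocks, 100) == (30, 2)

    def test_zero_when_half_never_reached(self):
        assert nga50([blk(0, 10)], 100) == (0, 0)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=500), min_size=0, max_size=50),
        st.integers(min_value=1, max_value=5_000),
    )
    def test_matches_brute_force_scan(self, lengths, ref_len):
        blocks = [blk(0, ln) for ln in lengths]
        got = nga50(blocks, ref_len)
        # oracle: literal definitions — NGA50 is the largest L such that
        # blocks of length >= L cover at least half the reference; LGA50 is
        # the minimal number of blocks whose total reaches half
        n = 0
        for ln in sorted(set(lengths), reverse=True):
            if sum(x for x in lengths if x >= ln) >= ref_len / 2:
                n = ln
                break
        l = 0
        acc = 0
        for i, ln in enumerate(sorted(lengths, reverse=True), start=1):
            acc += ln
            if acc >= ref_len / 2:
                l = i
                break
        assert got == (n, l)


class TestDuplicationCoverage:
    def test_perfect_block(self):
        b = [blk(0, 1000)]
        assert duplication_ratio(b, 1000) == 1.0
        assert coverage_fraction(b, 1000) == 1.0

    def test_two_identical_blocks(self):
        b = [blk(0, 1000), blk(0, 1000)]
        assert duplication_ratio(b, 1000) == 2.0
        assert coverage_fraction(b, 1000) == 1.0

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=900),
                st.integers(min_value=1, max_value=100),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_matches_interval_union_oracle(self, raw):
        blocks = [blk(s, s + ln) for s, ln in raw]
        covered = sum(
            1
            for p in range(1000)
            if any(b.ref_start <= p < b.ref_end for b in blocks)
        )
        assert coverage_fraction(blocks, 1000) == pytest.approx(covered / 1000)
        total_q = sum(b.qry_end - b.qry_start for b in blocks)
        assert duplication_ratio(blocks, 1000) == pytest.approx(total_q / covered)
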