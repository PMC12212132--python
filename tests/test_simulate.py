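"""Simulator contracts: determinism, composition, truth round-trip,
coverage and copy-number accounting."""

import numpy as np
import pytest
from scipy import stats

from haplokit import simulate as sim


class TestAncestral:
    def test_single_base_boundary(self):
        seq = sim.simulate_ancestral(sim.RegionSpec(1, 0.5, 7))
        assert len(seq) == 1 and seq in "ACGT"

    def test_deterministic_for_fixed_seed(self):
        a = sim.simulate_ancestral(sim.RegionSpec(10_000, 0.5, 1))
        b = sim.simulate_ancestral(sim.RegionSpec(10_000, 0.5, 1))
        assert a == b

    def test_gc_fraction_matches_request(self):
        # binomial CI at n=1e6: 0.6 +/- ~4.9e-3 at z=10, inside the 0.01 band
        seq = sim.simulate_ancestral(sim.RegionSpec(1_000_000, 0.6, 2))
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.6) < 0.01

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            sim.RegionSpec(0, 0.5, 1)


class TestDeriveHaplotypes:
    def test_zero_rates_identity(self):
        anc = sim.simulate_ancestral(sim.RegionSpec(5_000, 0.4, 3))
        h1, h2, truth = sim.derive_haplotypes(anc, 0.0, 0.0, [], seed=3)
        assert h1 == anc and h2 == anc and truth == []

    def test_deletion_length_arithmetic(self):
        anc = sim.simulate_ancestral(sim.RegionSpec(20_000, 0.4, 4))
        dele = sim.make_deletion(anc, 10_000, 1469, "hap1")
        h1, h2, _ = sim.derive_haplotypes(anc, 0.0, 0.0, [dele], seed=4)
        assert len(h1) == len(anc) - 1469
        assert h2 == anc

    def test_snv_count_within_poisson_band(self):
        anc = sim.simulate_ancestral(sim.RegionSpec(1_000_000, 0.41, 5))
        _, _, truth = sim.derive_haplotypes(anc, 0.001, 0.0, [], seed=5)
        n = sum(1 for v in truth if v.vclass == "SNV")
        lo, hi = stats.poisson.ppf([0.005, 0.995], 1000)
        assert lo <= n <= hi

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_truth_round_trip(self, seed):
        anc = sim.simulate_ancestral(sim.RegionSpec(30_000, 0.41, seed))
        ins = sim.make_insertion(anc, 20_000, 968, "hap2", seed=seed)
        h1, h2, truth = sim.derive_haplotypes(anc, 0.002, 5e-4, [ins], seed=seed)
        assert sim.apply_variants(anc, truth, "hap1") == h1
        assert sim.apply_variants(anc, truth, "hap2") == h2
        assert truth == sorted(truth, key=lambda v: v.pos)

    def test_heterozygous_sites_differ_between_haplotypes(self):
        anc = sim.simulate_ancestral(sim.RegionSpec(50_000, 0.41, 6))
        h1, h2, truth = sim.derive_haplotypes(anc, 0.002, 0.0, [], seed=6)
        for v in truth:
            carrier = h1 if v.genotype == "hap1" else h2
            assert v.ref_allele != v.alt_allele

    def test_overlapping_svs_rejected(self):
        anc = sim.simulate_ancestral(sim.RegionSpec(10_000, 0.4, 7))
        a = sim.make_deletion(anc, 5_000, 100, "hap1")
        b = sim.make_deletion(anc, 5_050, 100, "hap2")
        with pytest.raises(ValueError, match="overlap"):
            sim.derive_haplotypes(anc, 0.0, 0.0, [a, b], seed=7)

    def test_sv_outside_region_rejected(self):
        anc = sim.simulate_ancestral(sim.RegionSpec(1_000, 0.4, 8))
        with pytest.raises(ValueError):
            sim.make_deletion(anc, 950, 100, "hap1")


class TestLongReads:
    def test_tiny_depth_boundary(self):
        hap = sim.simulate_ancestral(sim.RegionSpec(100_000, 0.4, 9))
        reads = sim.simulate_long_reads(hap, 0.0001, seed=9)
        assert len(reads) <= 2

    def test_error_free_reads_are_exact_substrings(self):
        hap = sim.simulate_ancestral(sim.RegionSpec(60_000, 0.4, 10))
        for r in sim.simulate_long_reads(hap, 5, seed=10):
            s, e = r.truth_interval
            assert r.sequence == hap[s:e]

    def test_mean_coverage_near_target(self):
        hap = sim.simulate_ancestral(sim.RegionSpec(500_000, 0.4, 11))
        reads = sim.simulate_long_reads(hap, 30, 10_000, 1_000, seed=11)
        cov = sum(len(r.sequence) for r in reads) / len(hap)
        assert 28.5 <= cov <= 31.5

    def test_substitution_rate_applied(self):
        hap = sim.simulate_ancestral(sim.RegionSpec(100_000, 0.4, 12))
        reads = sim.simulate_long_reads(hap, 10, error_rate=0.01, seed=12)
        mism = total = 0
        for r in reads:
            s, e = r.truth_interval
            truth_seq = hap[s:e]
            mism += sum(a != b for a, b in zip(r.sequence, truth_seq))
            total += len(r.sequence)
        lo, hi = stats.binom.ppf([0.001, 0.999], total, 0.01)
        assert lo <= mism <= hi

    def test_deterministic(self):
        hap = sim.simulate_ancestral(sim.RegionSpec(50_000, 0.4, 13))
        a = sim.simulate_long_reads(hap, 5, error_rate=0.002, seed=13)
        b = sim.simulate_long_reads(hap, 5, error_rate=0.002, seed=13)
        assert a == b


class TestShortReadWgs:
    @pytest.mark.parametrize(
        "cn,expected,tol",
        [((1, 1), 1.0, 0.05), ((3, 1), 3.0, 0.15)],
    )
    def test_read_count_ratio_tracks_copy_number(self, region100k, cn, expected, tol):
        _, hap1, hap2, _ = region100k
        pairs = sim.simulate_short_read_wgs(
            hap1, hap2, sim.CopyNumberSpec(*cn), 20.0, seed=14
        )
        n1 = sum(1 for p in pairs if p.truth_haplotype == "hap1")
        n2 = sum(1 for p in pairs if p.truth_haplotype == "hap2")
        assert abs(n1 / n2 - expected) <= tol

    def test_zero_depth_empty(self, region100k):
        _, hap1, hap2, _ = region100k
        assert (
            sim.simulate_short_read_wgs(hap1, hap2, sim.CopyNumberSpec(1, 1), 0.0)
            == []
        )

    def test_both_copies_zero_rejected(self):
        with pytest.raises(ValueError):
            sim.CopyNumberSpec(0, 0)

    def test_mates_are_substrings_of_source(self, region100k):
        from haplokit.util import revcomp

        _, hap1, hap2, _ = region100k
        pairs = sim.simulate_short_read_wgs(
            hap1, hap2, sim.CopyNumberSpec(1, 1), 0.2, seed=15
        )
        assert pairs
        for p in pairs[:200]:
            src = hap1 if p.truth_haplotype == "hap1" else hap2
            assert p.seq1 in src and revcomp(p.seq2) in src
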