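"""Personal references, zero-edit filtering, depth liftover and the log2
copy-ratio profile."""

import numpy as np
import pytest

from haplokit import simulate as sim
from haplokit.aneuploidy import (
    ExactMatcher,
    build_personal_reference,
    depth_profile,
    log2_ratio_profile,
    match_reads,
    mhc_alignment_gain,
    project_depth,
    unique_zero_edit_filter,
)
from haplokit.pipeline import profile_copy_ratio
from haplokit.util import revcomp
from haplokit.variants import anchor_align


class TestPersonalReference:
    def test_identity_when_hap_equals_excised_segment(self):
        ref = sim.simulate_ancestral(sim.RegionSpec(20_000, 0.4, 71))
        seg = ref[5_000:15_000]
        pr = build_personal_reference(ref, (5_000, 15_000), seg, seg)
        assert pr.seq_hap1 == ref and pr.seq_hap2 == ref

    def test_length_identity_with_deletion(self):
        ref = sim.simulate_ancestral(sim.RegionSpec(20_000, 0.4, 72))
        seg = ref[5_000:15_000]
        shorter = seg[:4_000] + seg[4_000 + 1_469:]
        pr = build_personal_reference(ref, (5_000, 15_000), shorter, seg)
        assert len(pr.seq_hap1) == len(ref) - 1_469
        assert pr.seq_hap1[:5_000] == ref[:5_000]
        assert pr.seq_hap1[-5_000:] == ref[-5_000:]

    def test_zero_length_interval_rejected(self):
        ref = "ACGT" * 100
        with pytest.raises(ValueError):
            build_personal_reference(ref, (10, 10), "ACGT", "ACGT")


class TestZeroEditFilter:
    def test_unique_match_kept_shared_dropped(self):
        a1 = {"r1": (0, 100), "r2": (50, 150), "r3": None}
        a2 = {"r1": None, "r2": (60, 160), "r3": None}
        k1, k2 = unique_zero_edit_filter(a1, a2)
        assert k1 == {"r1": (0, 100)}
        assert k2 == {}

    def test_mismatching_read_dropped_everywhere(self):
        k1, k2 = unique_zero_edit_filter({"r": None}, {"r": None})
        assert k1 == {} and k2 == {}

    def test_exact_matcher_both_strands(self):
        seq = sim.simulate_ancestral(sim.RegionSpec(5_000, 0.45, 73))
        m = ExactMatcher(seq)
        assert m.match(seq[1_000:1_150]) == (1_000, 1_150)
        assert m.match(revcomp(seq[2_000:2_150])) == (2_000, 2_150)
        assert m.match("N" * 150) is None

    def test_reads_unique_to_their_haplotype_survive(self):
        anc = sim.simulate_ancestral(sim.RegionSpec(50_000, 0.41, 74))
        hap1, hap2, _ = sim.derive_haplotypes(anc, 0.002, 0.0, [], seed=74)
        pairs = sim.simulate_short_read_wgs(
            hap1, hap2, sim.CopyNumberSpec(1, 1), 2.0, seed=74
        )
        m1 = match_reads(pairs, hap1)
        m2 = match_reads(pairs, hap2)
        k1, k2 = unique_zero_edit_filter(m1, m2)
        by_id = {p.id: p.truth_haplotype for p in pairs}
        assert all(by_id[rid.rsplit("/", 1)[0]] == "hap1" for rid in k1)
        assert all(by_id[rid.rsplit("/", 1)[0]] == "hap2" for rid in k2)


class TestDepthProjection:
    def test_identity_chain_preserves_depth(self):
        seq = sim.simulate_ancestral(sim.RegionSpec(20_000, 0.4, 75))
        chain = anchor_align(seq, seq)
        depth = depth_profile([(0, 10_000), (5_000, 15_000)], len(seq))
        out = project_depth(depth, chain)
        assert np.array_equal(out, depth)

    def test_deletion_region_undefined(self):
        anc = sim.simulate_ancestral(sim.RegionSpec(30_000, 0.4, 76))
        dele = sim.make_deletion(anc, 15_000, 1_469, "hap1")
        hap1, _, _ = sim.derive_haplotypes(anc, 0.0, 0.0, [dele], seed=76)
        chain = anchor_align(hap1, anc)
        depth = np.ones(len(hap1))
        out = project_depth(depth, chain)
        assert np.isnan(out[15_100:16_300]).all()
        assert np.nansum(out) == pytest.approx(len(hap1))

    def test_block_interior_sums_conserved(self):
        anc = sim.simulate_ancestral(sim.RegionSpec(40_000, 0.4, 77))
        hap1, _, _ = sim.derive_haplotypes(anc, 0.001, 5e-4, [], seed=77)
        chain = anchor_align(hap1, anc)
        rng = np.random.default_rng(77)
        depth = rng.poisson(20, len(hap1)).astype(float)
        out = project_depth(depth, chain)
        for b in chain.blocks:
            assert out[b.ref_start : b.ref_end].sum() == pytest.approx(
                depth[b.qry_start : b.qry_end].sum()
            )


class TestLog2Profile:
    def test_equal_depth_gives_unit_ratio(self):
        d = np.full(50_000, 20.0)
        prof = log2_ratio_profile(d, d.copy(), list(range(0, 50_000, 997)))
        assert np.allclose(prof.log2_ratio, 0.0)
        assert prof.overall_ratio == pytest.approx(1.0)

    def test_three_to_one_constant_depth(self):
        d2 = np.full(50_000, 20.0)
        d1 = 3 * d2
        prof = log2_ratio_profile(d1, d2, list(range(0, 50_000, 997)), eps=0.0)
        assert np.allclose(prof.log2_ratio, np.log2(3.0))
        assert prof.overall_ratio == pytest.approx(3.0)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(78)
        d1 = rng.poisson(40, 60_000).astype(float)
        d2 = rng.poisson(20, 60_000).astype(float)
        pos = list(range(100, 60_000, 500))
        a = log2_ratio_profile(d1, d2, pos)
        b = log2_ratio_profile(d2, d1, pos)
        assert np.allclose(a.log2_ratio, -b.log2_ratio)
        assert a.overall_ratio == pytest.approx(1 / b.overall_ratio)

    def test_gap_fill_stays_in_computed_range(self):
        d1 = np.full(100_000, 40.0)
        d2 = np.full(100_000, 20.0)
        pos = [5_000, 95_000]  # only first and last windows computed
        prof = log2_ratio_profile(d1, d2, pos)
        assert prof.gap_filled.sum() == len(prof.log2_ratio) - 2
        lo, hi = prof.log2_ratio[[0, -1]].min(), prof.log2_ratio[[0, -1]].max()
        assert ((prof.log2_ratio >= lo) & (prof.log2_ratio <= hi)).all()

    def test_no_variant_positions_rejected(self):
        d = np.full(1_000, 1.0)
        with pytest.raises(ValueError):
            log2_ratio_profile(d, d, [])

    def test_copy_number_recovered_from_simulated_wgs(self):
        # end-to-end sub-pipeline on a 150 kb region at 20x per copy
        anc = sim.simulate_ancestral(sim.RegionSpec(150_000, 0.41, 79))
        hap1, hap2, truth = sim.derive_haplotypes(anc, 0.001, 1e-4, [], seed=79)
        fl = sim.simulate_ancestral(sim.RegionSpec(5_000, 0.41, 179))
        fr = sim.simulate_ancestral(sim.RegionSpec(5_000, 0.41, 279))
        pairs = sim.simulate_short_read_wgs(
            fl + hap1 + fr, fl + hap2 + fr, sim.CopyNumberSpec(2, 1), 20.0, seed=79
        )
        result = profile_copy_ratio(
            fl + anc + fr,
            (5_000, 155_000),
            hap1,
            hap2,
            pairs,
            variant_positions=[v.pos for v in truth],
            reference_region=anc,
            compute_gain=True,
        )
        assert result["profile"].overall_ratio == pytest.approx(2.0, rel=0.05)
        # divergent haplotypes: the personal reference recovers strictly
        # more region reads than the ancestral reference
        assert result["alignment_gain_pct"] > 0


def test_plot_profile_writes_figure(tmp_path):
    from haplokit.aneuploidy import plot_profile

    d1 = np.full(40_000, 40.0)
    d2 = np.full(40_000, 20.0)
    prof = log2_ratio_profile(d1, d2, list(range(0, 40_000, 500)))
    out = tmp_path / "profile.png"
    plot_profile(prof, out, genes=[(5_000, 8_000, "geneA")])
    assert out.stat().st_size > 0


class TestAlignmentGain:
    def test_equal_counts_zero(self):
        assert mhc_alignment_gain(10_000, 10_000) == 0.0

    def test_three_percent(self):
        assert mhc_alignment_gain(10_000, 10_300) == pytest.approx(3.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            mhc_alignment_gain(0, 10)
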