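"""Shared fixtures: one moderately sized diploid simulation reused across
modules (session scope keeps the suite fast)."""

from __future__ import annotations

import pytest

from haplokit import simulate as sim


@pytest.fixture(scope="session")
def region100k():
    """100 kb diploid region with 1 SNV/kb, sparse indels and a planted
    1469 bp deletion on haplotype 1."""
    anc = sim.simulate_ancestral(sim.RegionSpec(100_000, 0.41, 11))
    dele = sim.make_deletion(anc, 50_000, 1469, "hap1")
    hap1, hap2, truth = sim.derive_haplotypes(anc, 0.001, 1e-4, [dele], seed=11)
    return anc, hap1, hap2, truth


@pytest.fixture(scope="session")
def long_reads_100k(region100k):
    """Error-free 30x long reads from both haplotypes of region100k."""
    _, hap1, hap2, _ = region100k
    reads = sim.simulate_long_reads(hap1, 30, seed=11, hap_label="hap1")
    reads += sim.simulate_long_reads(hap2, 30, seed=12, hap_label="hap2")
    return reads
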