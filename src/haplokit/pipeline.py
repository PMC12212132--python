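"""End-to-end orchestration: simulate → phase → partition → assemble →
evaluate → callvars → aneuploidy, with a JSON manifest.

Every stage is deterministic given the run configuration, so identical
config + seed reproduces identical outputs byte for byte, and re-running a
prefix of the stage list is cheap.  The manifest echoes every parameter and
per-stage counts so filter behaviour is auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import aneuploidy as an
from . import assembly as asm
from . import evaluate as ev
from . import io as hio
from . import partition as pt
from . import phasing as ph
from . import simulate as sim
from . import variants as var
from .locate import ReadLocator

STAGES = ["simulate", "phase", "partition", "assemble", "evaluate", "callvars", "aneuploidy"]


@dataclass
class RunConfig:
    """All pipeline parameters.  Defaults follow the targeted-assembly
    workflow where it states a value: 10 kb windows, 30x per-window coverage
    target, 50 kb contig filter, 50 bp SV threshold, k-mer collision rate
    0.001, 10 kb minimum called region."""

    region_length: int = 200_000
    gc_content: float = 0.41
    seed: int = 0
    snv_rate: float = 0.001
    indel_rate: float = 1e-4
    # structural variants: (kind 'DEL'|'INS', position, length, genotype)
    sv_specs: tuple = ()
    cn: tuple[int, int] = (1, 1)
    long_depth: float = 30.0
    mean_len: int = 10_000
    len_sd: int = 1_000
    long_error: float = 0.0
    depth_per_copy: float = 20.0
    read_len: int = 150
    short_error: float = 0.0
    fn_frac: float = 0.02
    fp_per_bp: float = 2e-5
    window_size: int = 10_000
    target_cov: float = 30.0
    min_contig_len: int = 50_000
    min_overlap: int = 2_000
    collision_rate: float = 0.001
    haploid_threshold: float = 0.05
    min_region: int = 10_000
    flank: int = 10_000
    ratio_eps: float = 0.5
    make_plots: bool = True


def _svs_from_specs(config: RunConfig, ancestral: str) -> list[sim.TruthVariant]:
    svs = []
    for kind, pos, length, gt in config.sv_specs:
        if kind == "DEL":
            svs.append(sim.make_deletion(ancestral, int(pos), int(length), gt))
        elif kind == "INS":
            svs.append(
                sim.make_insertion(ancestral, int(pos), int(length), gt, seed=config.seed)
            )
        else:
            raise ValueError(f"unknown SV kind {kind!r}")
    return svs


def _scaffold(assembly: asm.Assembly, reference: str) -> str:
    """Concatenate contigs in reference order (naive gap-free scaffolding)."""
    placed = []
    for c in assembly.contigs:
        try:
            chain = var.anchor_align(c.sequence, reference)
            placed.append((chain.blocks[0].ref_start, c.sequence))
        except ValueError:
            continue
    placed.sort()
    return "".join(s for _, s in placed)


def run_pipeline(config: RunConfig, outdir, last_stage: str = "aneuploidy") -> dict:
    """Run stages in order through `last_stage`; returns (and writes) the manifest."""
    if last_stage not in STAGES:
        raise ValueError(f"unknown stage {last_stage!r}")
    out = hio.ensure_dir(outdir)
    upto = STAGES.index(last_stage)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def done(stage: str) -> bool:
        return STAGES.index(stage) > upto

    # ------------------------------------------------------------- simulate
    L = config.region_length
    spec = sim.RegionSpec(L, config.gc_content, config.seed)
    ancestral = sim.simulate_ancestral(spec)
    svs = _svs_from_specs(config, ancestral)
    hap1, hap2, truth = sim.derive_haplotypes(
        ancestral, config.snv_rate, config.indel_rate, svs, seed=config.seed
    )
    reads = sim.simulate_long_reads(
        hap1, config.long_depth, config.mean_len, config.len_sd,
        config.long_error, config.seed, "hap1",
    ) + sim.simulate_long_reads(
        hap2, config.long_depth, config.mean_len, config.len_sd,
        config.long_error, config.seed + 1, "hap2",
    )
    cn = sim.CopyNumberSpec(*config.cn)
    flank_l = sim.simulate_ancestral(
        sim.RegionSpec(config.flank, config.gc_content, config.seed + 101)
    )
    flank_r = sim.simulate_ancestral(
        sim.RegionSpec(config.flank, config.gc_content, config.seed + 102)
    )
    genome = flank_l + ancestral + flank_r
    pairs = sim.simulate_short_read_wgs(
        flank_l + hap1 + flank_r,
        flank_l + hap2 + flank_r,
        cn,
        config.depth_per_copy,
        config.read_len,
        error_rate=config.short_error,
        seed=config.seed,
    )
    callset_a = sim.noisy_callset(
        truth, ancestral, config.fn_frac, config.fp_per_bp, config.seed, "callset_noise_a"
    )
    callset_b = sim.noisy_callset(
        truth, ancestral, config.fn_frac, config.fp_per_bp, config.seed, "callset_noise_b"
    )
    hio.write_fasta(out / "region.fasta", [("region", ancestral)])
    hio.write_fasta(out / "haplotypes.fasta", [("hap1", hap1), ("hap2", hap2)])
    hio.write_fastq(out / "long_reads.fastq", reads)
    hio.write_truth_tsv(out / "long_reads.truth.tsv", reads)
    hio.write_phased_vcf(
        out / "truth.vcf", sim.truth_to_callset(truth), "region", L
    )
    hio.write_phased_vcf(out / "callset_a.vcf", callset_a, "region", L)
    hio.write_phased_vcf(out / "callset_b.vcf", callset_b, "region", L)
    hio.write_paired_fastq(out / "wgs_R1.fastq", out / "wgs_R2.fastq", pairs)
    manifest["stages"]["simulate"] = {
        "region_length": L,
        "n_truth_variants": len(truth),
        "n_truth_sv": sum(1 for v in truth if v.vclass == "SV"),
        "hap1_length": len(hap1),
        "hap2_length": len(hap2),
        "n_long_reads": len(reads),
        "n_short_pairs": len(pairs),
    }
    if done("phase"):
        return _finish(manifest, out)

    # ---------------------------------------------------------------- phase
    na = [ph.normalize_variant(v, ancestral) for v in callset_a]
    nb = [ph.normalize_variant(v, ancestral) for v in callset_b]
    consensus = ph.intersect_callsets(na, nb)
    ploidy = ph.classify_ploidy(consensus, L, config.haploid_threshold)
    hio.write_phased_vcf(out / "consensus.vcf", consensus, "region", L)
    manifest["stages"]["phase"] = {
        "callset_a": len(callset_a),
        "callset_b": len(callset_b),
        "consensus": len(consensus),
        "ploidy_mode": ploidy.mode,
        "het_per_kb": round(ploidy.density, 4),
    }
    if done("partition"):
        return _finish(manifest, out)

    # ------------------------------------------------------------ partition
    locator = ReadLocator(ancestral)
    alignments, unrecruited = pt.align_reads(reads, ancestral, locator=locator)
    aln_by_id = {a.read_id: a for a in alignments}
    recruited_ids = set(aln_by_id)
    if ploidy.mode == "diploid":
        parts = pt.partition_reads(alignments, consensus, ancestral)
    else:
        parts = {"hap1": recruited_ids.copy(), "hap2": set(), "untagged": set()}
    downsampled: dict[str, set[str]] = {}
    for label, ids in parts.items():
        ivs = [(rid, aln_by_id[rid].ref_start, aln_by_id[rid].ref_end) for rid in sorted(ids)]
        downsampled[label] = pt.downsample_longest_per_window(
            ivs, config.window_size, config.target_cov
        )
    all_ivs = [(a.read_id, a.ref_start, a.ref_end) for a in alignments]
    pt.window_coverage(all_ivs, L, config.window_size).to_csv(
        out / "window_coverage.tsv", sep="\t", index=False
    )
    manifest["stages"]["partition"] = {
        "recruited": len(recruited_ids),
        "unrecruited": len(unrecruited),
        **{f"n_{k}": len(v) for k, v in parts.items()},
        **{f"n_{k}_downsampled": len(v) for k, v in downsampled.items()},
    }
    if done("assemble"):
        return _finish(manifest, out)

    # ------------------------------------------------------------- assemble
    read_seq = {r.id: r.sequence for r in reads}
    all_read_tuples = sorted(read_seq.items())
    hap_labels = ["hap1", "hap2"] if ploidy.mode == "diploid" else ["hap1"]
    assemblies: dict[str, asm.Assembly] = {}
    for label in hap_labels:
        ids = sorted(downsampled[label] | downsampled["untagged"])
        round1 = [(rid, read_seq[rid]) for rid in ids]
        assembly, info = asm.assemble_haplotype(
            round1,
            all_read_tuples,
            recruited_ids,
            haplotype=label,
            min_overlap=config.min_overlap,
            min_contig_len=config.min_contig_len,
        )
        assemblies[label] = assembly
        manifest["stages"].setdefault("assemble", {})[label] = {
            **info,
            "contigs": len(assembly.contigs),
            "largest": assembly.largest,
            "total_length": assembly.total_length,
        }
        hio.write_fasta(
            out / f"assembly_{label}.fasta",
            [(f"{label}_{c.id}", c.sequence) for c in assembly.contigs],
        )
    if done("evaluate"):
        return _finish(manifest, out)

    # ------------------------------------------------------------- evaluate
    k_real, k_int = ev.optimal_k(L, config.collision_rate)
    chains: dict[str, list[tuple[var.AlignmentChain, asm.Contig]]] = {}
    rows = []
    read_seqs_all = [r.sequence for r in reads]
    for label, assembly in assemblies.items():
        per_contig = []
        for c in assembly.contigs:
            try:
                per_contig.append((var.anchor_align(c.sequence, ancestral), c))
            except ValueError:
                continue
        chains[label] = per_contig
        blocks = [
            var.AlignmentBlock(
                ch.blocks[0].ref_start,
                ch.blocks[-1].ref_end,
                ch.blocks[0].qry_start,
                ch.blocks[-1].qry_end,
            )
            for ch, _ in per_contig
        ]
        stats = ev.compute_kmer_stats(
            read_seqs_all, [c.sequence for c in assembly.contigs], k_int
        )
        n50, l50 = ev.nga50(blocks, L)
        rows.append(
            {
                "Haplotype": label,
                "Contigs": len(assembly.contigs),
                "Largest contig length (bp)": assembly.largest,
                "Total length (bp)": assembly.total_length,
                "Coverage (%)": round(100 * ev.coverage_fraction(blocks, L), 2),
                "NGA50": n50,
                "LGA50": l50,
                "Duplication ratio": round(ev.duplication_ratio(blocks, L), 4),
                "Kmer completeness (%)": round(100 * ev.kmer_completeness(stats), 2),
                "QV": round(ev.consensus_qv(stats), 1),
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "assembly_report.tsv", sep="\t", index=False)
    manifest["stages"]["evaluate"] = {
        "optimal_k": k_real,
        "counting_k": k_int,
        "report": rows,
    }
    if done("callvars"):
        return _finish(manifest, out)

    # ------------------------------------------------------------- callvars
    calls_by_hap: dict[str, list[var.CalledVariant]] = {}
    for label in hap_labels:
        seen = set()
        merged = []
        for chain, contig in chains[label]:
            for c in var.call_variants(
                chain, contig.sequence, ancestral, config.min_region, label
            ):
                if c.key not in seen:
                    seen.add(c.key)
                    merged.append(c)
        calls_by_hap[label] = sorted(merged, key=lambda c: c.key)
    all_calls = [c for cs in calls_by_hap.values() for c in cs]
    hio.write_calls_vcf(out / "calls.vcf", all_calls, "region", L)
    hio.write_sv_tsv(out / "sv_calls.tsv", all_calls, "region")
    var.variant_summary(calls_by_hap, L).to_csv(
        out / "variant_summary.tsv", sep="\t", index=False
    )
    manifest["stages"]["callvars"] = {
        label: {
            "n_calls": len(cs),
            "n_snv": sum(1 for c in cs if c.vclass == "SNV"),
            "n_indel": sum(1 for c in cs if c.vclass == "indel"),
            "n_sv": sum(1 for c in cs if c.vclass.startswith("SV")),
        }
        for label, cs in calls_by_hap.items()
    }
    if done("aneuploidy"):
        return _finish(manifest, out)

    # ----------------------------------------------------------- aneuploidy
    if ploidy.mode == "haploid":
        manifest["stages"]["aneuploidy"] = {
            "skipped": "haploid mode: no heterozygous depth ratio to profile"
        }
        return _finish(manifest, out)
    scaf1 = _scaffold(assemblies["hap1"], ancestral) or hap1
    scaf2 = _scaffold(assemblies["hap2"], ancestral) or hap2
    interval = (config.flank, config.flank + L)
    result = profile_copy_ratio(
        genome,
        interval,
        scaf1,
        scaf2,
        pairs,
        variant_positions=[c.ref_pos for c in all_calls],
        window=config.window_size,
        eps=config.ratio_eps,
        reference_region=ancestral,
    )
    profile = result["profile"]
    hio.write_bedgraph(out / "depth_hap1_ref.bedgraph", result["depth1_ref"], "region")
    hio.write_bedgraph(out / "depth_hap2_ref.bedgraph", result["depth2_ref"], "region")
    pd.DataFrame(
        {
            "start": profile.window_starts,
            "end": np.minimum(profile.window_starts + profile.window_size, L),
            "log2_ratio": np.round(profile.log2_ratio, 4),
            "gap_filled": profile.gap_filled.astype(int),
        }
    ).to_csv(out / "copy_ratio_profile.tsv", sep="\t", index=False)
    if config.make_plots:
        an.plot_profile(profile, out / "copy_ratio_profile.png")
    manifest["stages"]["aneuploidy"] = {
        "overall_ratio": round(profile.overall_ratio, 4),
        "n_windows": len(profile.log2_ratio),
        "n_gap_filled": int(profile.gap_filled.sum()),
        "region_alignment_gain_pct": round(result["alignment_gain_pct"], 3),
        "kept_hap1": result["kept_hap1"],
        "kept_hap2": result["kept_hap2"],
    }
    return _finish(manifest, out)


def profile_copy_ratio(
    genome: str,
    interval: tuple[int, int],
    hap1: str,
    hap2: str,
    pairs,
    variant_positions,
    window: int = 10_000,
    eps: float = 0.5,
    reference_region: str | None = None,
    compute_gain: bool = True,
) -> dict:
    """Full aneuploidy sub-pipeline on in-memory inputs.

    Builds the two personal references, exact-matches every mate against
    both, applies the unique zero-edit filter, computes per-base depth on
    each embedded haplotype, lifts it to reference-region coordinates through
    the anchor chain, and profiles the windowed log2 depth ratio.
    """
    personal = an.build_personal_reference(genome, interval, hap1, hap2)
    m1 = an.match_reads(pairs, personal.seq_hap1)
    m2 = an.match_reads(pairs, personal.seq_hap2)
    kept1, kept2 = an.unique_zero_edit_filter(m1, m2)
    region = (
        reference_region
        if reference_region is not None
        else genome[interval[0] : interval[1]]
    )
    s = interval[0]
    out = {}
    depths_ref = []
    for hap, kept in ((hap1, kept1), (hap2, kept2)):
        hap_iv = (s, s + len(hap))
        placements = [
            (max(a - s, 0), min(b - s, len(hap)))
            for a, b in kept.values()
            if b > hap_iv[0] and a < hap_iv[1]
        ]
        depth = an.depth_profile(placements, len(hap))
        chain = var.anchor_align(hap, region)
        depths_ref.append(an.project_depth(depth, chain))
    profile = an.log2_ratio_profile(
        depths_ref[0], depths_ref[1], variant_positions, window=window, eps=eps
    )
    gain = float("nan")
    if compute_gain:
        # a mate counts as region-aligned if it has a zero-edit placement
        # overlapping the target interval of the given reference
        m_ref = an.match_reads(pairs, genome)
        e = interval[1]
        n_ref = sum(
            1 for iv in m_ref.values() if iv is not None and iv[1] > s and iv[0] < e
        )
        n_personal = 0
        for rid in set(m1) | set(m2):
            a = m1.get(rid)
            b = m2.get(rid)
            hit_a = a is not None and a[1] > s and a[0] < s + len(hap1)
            hit_b = b is not None and b[1] > s and b[0] < s + len(hap2)
            if hit_a or hit_b:
                n_personal += 1
        gain = an.mhc_alignment_gain(max(n_ref, 1), n_personal)
    out.update(
        {
            "profile": profile,
            "depth1_ref": depths_ref[0],
            "depth2_ref": depths_ref[1],
            "kept_hap1": len(kept1),
            "kept_hap2": len(kept2),
            "alignment_gain_pct": gain,
        }
    )
    return out


def _finish(manifest: dict, out: Path) -> dict:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
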