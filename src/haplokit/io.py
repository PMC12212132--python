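"""File-format glue: FASTA/FASTQ via Biopython, VCF 4.2 read/write (pysam
for parsing), and small TSV/BED writers used by the pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phasing import PhasedVariant
from .simulate import PairedRead, SimulatedRead
from .variants import CalledVariant


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads: Sequence[SimulatedRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_paired_fastq(path1, path2, pairs: Sequence[PairedRead]) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")


def write_truth_tsv(path, reads: Sequence[SimulatedRead]) -> None:
    """Sidecar truth labels: read_id, haplotype, start, end (haplotype coords)."""
    with open(path, "w") as fh:
        fh.write("read_id\thaplotype\tstart\tend\n")
        for r in reads:
            s, e = r.truth_interval
            fh.write(f"{r.id}\t{r.truth_haplotype}\t{s}\t{e}\n")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=haplokit
##contig=<ID={contig},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=String,Description="Phase set">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_phased_vcf(
    path,
    variants: Sequence[PhasedVariant],
    contig: str,
    contig_length: int,
    sample: str = "sim",
) -> None:
    """Phased heterozygous callset as VCF 4.2 (1-based, GT like 1|0, PS tag)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contig=contig, length=contig_length, sample=sample))
        for v in sorted(variants, key=lambda x: x.key):
            fh.write(
                f"{contig}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t."
                f"\tGT:PS\t{v.genotype}:{v.phase_set}\n"
            )


def read_phased_vcf(path) -> list[PhasedVariant]:
    """Phased heterozygous records of a VCF (sites with unphased or
    homozygous genotypes are skipped)."""
    out: list[PhasedVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            sample = rec.samples[0]
            gt = sample["GT"]
            if gt is None or None in gt or len(gt) != 2 or not sample.phased:
                continue
            a1, a2 = gt
            if a1 == a2:
                continue
            alleles = (rec.ref,) + tuple(rec.alts or ())
            ps = str(sample.get("PS", "ps0"))
            alt = alleles[max(a1, a2)]
            out.append(
                PhasedVariant(
                    pos=rec.start,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    hap1_allele=alleles[a1],
                    hap2_allele=alleles[a2],
                    phase_set=ps,
                )
            )
    return out


def write_calls_vcf(
    path, calls: Sequence[CalledVariant], contig: str, contig_length: int
) -> None:
    """Assembly-derived calls as VCF 4.2, one sample column per haplotype label."""
    with open(path, "w") as fh:
        fh.write(
            "##fileformat=VCFv4.2\n##source=haplokit-callvars\n"
            f"##contig=<ID={contig},length={contig_length}>\n"
            '##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant class">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Net length change">\n'
            '##INFO=<ID=HAP,Number=1,Type=String,Description="Haplotype of origin">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        for c in sorted(calls, key=lambda x: (x.ref_pos, x.haplotype)):
            fh.write(
                f"{contig}\t{c.ref_pos + 1}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\tPASS"
                f"\tVCLASS={c.vclass};SVLEN={c.size};HAP={c.haplotype}\n"
            )


def write_sv_tsv(path, calls: Sequence[CalledVariant], contig: str) -> None:
    """Structural calls as a BEDPE-like TSV (0-based starts)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tsize\thaplotype\n")
        for c in sorted(calls, key=lambda x: (x.ref_pos, x.haplotype)):
            if not c.vclass.startswith("SV"):
                continue
            end = c.ref_pos + len(c.ref_allele)
            fh.write(
                f"{contig}\t{c.ref_pos}\t{end}\t{c.vclass}\t{c.size}\t{c.haplotype}\n"
            )


def write_bedgraph(path, values, contig: str) -> None:
    """Dense per-base track compressed to runs (BedGraph)."""
    import numpy as np

    vals = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        if len(vals) == 0:
            return
        run_start = 0
        cur = vals[0]
        for i in range(1, len(vals)):
            same = (vals[i] == cur) or (np.isnan(vals[i]) and np.isnan(cur))
            if not same:
                v = "nan" if np.isnan(cur) else f"{cur:g}"
                fh.write(f"{contig}\t{run_start}\t{i}\t{v}\n")
                run_start, cur = i, vals[i]
        v = "nan" if np.isnan(cur) else f"{cur:g}"
        fh.write(f"{contig}\t{run_start}\t{len(vals)}\t{v}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
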