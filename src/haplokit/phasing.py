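"""Consensus phasing: variant normalization, callset intersection, ploidy mode.

Two independently produced phased heterozygous callsets (in the motivating
workflow: one from long reads, one from linked short reads) are normalized to
a canonical left-aligned minimal representation and intersected on
(position, ref allele, alt allele).  Sites seen by both callers form the
consensus set used for read haplotagging.  A region with almost no
heterozygosity (loss of heterozygosity) is processed in haploid mode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class PhasedVariant:
    """A phased heterozygous site.

    Coordinates are 0-based.  ``hap1_allele``/``hap2_allele`` are the literal
    allele strings carried by each haplotype and must differ (heterozygous).
    """

    pos: int
    ref_allele: str
    alt_allele: str
    hap1_allele: str
    hap2_allele: str
    phase_set: str = "ps0"

    def __post_init__(self):
        if not self.ref_allele:
            raise ValueError("ref_allele must be non-empty")
        if self.hap1_allele == self.hap2_allele:
            raise ValueError("site is not heterozygous: identical haplotype alleles")
        alleles = {self.ref_allele, self.alt_allele}
        if {self.hap1_allele, self.hap2_allele} != alleles:
            raise ValueError("haplotype alleles must be {ref, alt}")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref_allele, self.alt_allele)

    @property
    def genotype(self) -> str:
        """'1|0' if haplotype 1 carries the alternate allele, else '0|1'."""
        return "1|0" if self.hap1_allele == self.alt_allele else "0|1"


@dataclass(frozen=True)
class PloidyMode:
    mode: str  # 'diploid' | 'haploid'
    n_het: int
    density: float  # heterozygous sites per kb


def normalize_variant(v: PhasedVariant, reference: str) -> PhasedVariant:
    """Return the left-aligned, parsimony-trimmed representation of ``v``.

    Standard normalization: trim shared suffix bases, left-shift indels while
    their final bases match the preceding reference base, then trim the shared
    prefix.  Idempotent; raises if the stated ref allele disagrees with the
    reference sequence.
    """
    pos, ref, alt = v.pos, v.ref_allele, v.alt_allele
    if reference[pos : pos + len(ref)] != ref:
        raise ValueError(
            f"ref allele {ref!r} does not match reference at position {pos}"
        )
    # 1) shrink from the right, extending left through the reference when one
    #    allele would become empty (classic left-align loop)
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif len(ref) != len(alt) and ref[-1] == alt[-1] and pos > 0:
            base = reference[pos - 1]
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos -= 1
        else:
            break
    # 2) trim shared prefix, keeping one anchor base for indels
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    hap1 = alt if v.hap1_allele == v.alt_allele else ref
    hap2 = alt if hap1 == ref else ref
    return replace(
        v, pos=pos, ref_allele=ref, alt_allele=alt, hap1_allele=hap1, hap2_allele=hap2
    )


def is_normalized(v: PhasedVariant, reference: str) -> bool:
    return normalize_variant(v, reference).key == v.key


def split_multiallelic(
    records: Iterable[tuple[int, str, Sequence[str], str, str]],
) -> list[PhasedVariant]:
    """Split (pos, ref, alts, hap1_allele, hap2_allele) records into bi-allelic
    PhasedVariants, one per alternate allele present on a haplotype."""
    out = []
    for pos, ref, alts, h1, h2 in records:
        for alt in alts:
            if alt in (h1, h2) and alt != ref:
                other = h2 if alt == h1 else h1
                # represent the partner allele as ref for this bi-allelic record
                out.append(
                    PhasedVariant(
                        pos,
                        ref,
                        alt,
                        hap1_allele=alt if alt == h1 else ref,
                        hap2_allele=alt if alt == h2 else ref,
                    )
                )
    return out


def intersect_callsets(
    a: Iterable[PhasedVariant],
    b: Iterable[PhasedVariant],
    reference: str | None = None,
) -> list[PhasedVariant]:
    """Consensus of two phased callsets, matched on (pos, ref, alt).

    Phase orientation of the output is taken from callset ``a`` (by
    convention the long-read callset).  When a reference is supplied, inputs
    are checked to be in normalized representation first.
    """
    a = list(a)
    b = list(b)
    if reference is not None:
        for v in list(a) + list(b):
            if not is_normalized(v, reference):
                raise ValueError(
                    f"unnormalized variant at pos {v.pos}: run normalize_variant first"
                )
    keys_b = {v.key for v in b}
    return sorted((v for v in a if v.key in keys_b), key=lambda v: v.key)


def classify_ploidy(
    consensus: Sequence[PhasedVariant],
    region_length: int,
    threshold: float = 0.05,
) -> PloidyMode:
    """Haploid iff heterozygous density (sites/kb) is strictly below threshold.

    Regions with loss of heterozygosity yield almost no consensus sites and
    are assembled as a single haplotype from all reads.
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    n = len(consensus)
    density = n / (region_length / 1000.0)
    mode = "haploid" if density < threshold else "diploid"
    return PloidyMode(mode=mode, n_het=n, density=density)
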