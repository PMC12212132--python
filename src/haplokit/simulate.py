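"""Synthetic diploid data generator.

Produces everything the downstream stages consume, with exactly known truth:
an ancestral region sequence, two haplotypes differing by heterozygous
SNVs/small indels plus explicitly planted structural variants, length-
distributed low-error long reads with per-read truth labels, copy-number-
weighted paired short reads, and noised phased callsets for the consensus
stage.  All randomness flows through per-operation streams keyed on the user
seed, so any stage can be regenerated independently and reproducibly.

Coordinates are 0-based half-open throughout.  Variants use anchored
VCF-style alleles (an indel's ref and alt share their first base).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phasing import PhasedVariant
from .util import BASES, revcomp, rng_for

SV_MIN_SIZE = 50  # net length difference, bp, at and above which an event is an SV


@dataclass(frozen=True)
class RegionSpec:
    """Target region stand-in: length, GC composition and seed."""

    length: int
    gc_content: float = 0.41
    seed: int = 0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("region length must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant with known haplotype assignment.

    genotype is 'hap1', 'hap2' (heterozygous) or 'both' (homozygous alt).
    """

    pos: int
    ref_allele: str
    alt_allele: str
    genotype: str

    def __post_init__(self):
        if self.genotype not in ("hap1", "hap2", "both"):
            raise ValueError(f"bad genotype {self.genotype!r}")

    @property
    def size(self) -> int:
        return abs(len(self.alt_allele) - len(self.ref_allele))

    @property
    def vclass(self) -> str:
        if self.size == 0:
            return "SNV"
        return "SV" if self.size >= SV_MIN_SIZE else "indel"

    @property
    def end(self) -> int:  # half-open end on the ancestral sequence
        return self.pos + len(self.ref_allele)


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    sequence: str
    truth_haplotype: str
    truth_interval: tuple[int, int]  # half-open, on the source haplotype
    error_rate_applied: float = 0.0


@dataclass(frozen=True)
class PairedRead:
    """A short-read pair (FR orientation) with its truth fragment interval."""

    id: str
    seq1: str
    seq2: str
    truth_haplotype: str
    fragment: tuple[int, int]


@dataclass(frozen=True)
class CopyNumberSpec:
    copies_hap1: int
    copies_hap2: int

    def __post_init__(self):
        if self.copies_hap1 < 0 or self.copies_hap2 < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.copies_hap1 == 0 and self.copies_hap2 == 0:
            raise ValueError("at least one haplotype must be present")


def simulate_ancestral(spec: RegionSpec) -> str:
    """I.i.d. ancestral sequence with the requested GC fraction."""
    rng = rng_for(spec.seed, "ancestral")
    gc = spec.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    idx = rng.choice(4, size=spec.length, p=p)
    return bytes(np.frombuffer(BASES.encode(), dtype=np.uint8)[idx]).decode()


def make_deletion(ancestral: str, pos: int, length: int, genotype: str) -> TruthVariant:
    """Anchored deletion of `length` bp starting after `pos`."""
    if pos < 0 or pos + 1 + length > len(ancestral):
        raise ValueError("deletion outside region")
    return TruthVariant(
        pos=pos,
        ref_allele=ancestral[pos : pos + 1 + length],
        alt_allele=ancestral[pos],
        genotype=genotype,
    )


def make_insertion(
    ancestral: str,
    pos: int,
    insert: str | int,
    genotype: str,
    seed: int = 0,
) -> TruthVariant:
    """Anchored insertion after `pos`; `insert` is a sequence or a length to draw."""
    if pos < 0 or pos >= len(ancestral):
        raise ValueError("insertion outside region")
    if isinstance(insert, int):
        rng = np.random.default_rng([seed, 99])
        insert = "".join(rng.choice(list(BASES), size=insert))
    return TruthVariant(
        pos=pos,
        ref_allele=ancestral[pos],
        alt_allele=ancestral[pos] + insert,
        genotype=genotype,
    )


def _overlaps(iv: tuple[int, int], occupied: list[tuple[int, int]]) -> bool:
    return any(s < iv[1] and iv[0] < e for s, e in occupied)


def derive_haplotypes(
    ancestral: str,
    snv_rate: float = 0.001,
    indel_rate: float = 0.0001,
    sv_list: list[TruthVariant] | None = None,
    seed: int = 0,
) -> tuple[str, str, list[TruthVariant]]:
    """Derive two haplotypes from the ancestral sequence.

    Heterozygous SNVs and small indels (1–10 bp, geometric lengths) are placed
    at the given per-bp rates and assigned to a haplotype at random; SVs are
    never random — only the explicit `sv_list` is planted, so the truth set is
    exactly known.  Returns (hap1, hap2, truth sorted by position), where
    applying `truth` to the ancestral reproduces both haplotypes bit-exactly.
    """
    for r in (snv_rate, indel_rate):
        if not 0.0 <= r <= 0.05:
            raise ValueError("variant rates must lie in [0, 0.05]")
    L = len(ancestral)
    sv_list = sorted(sv_list or [], key=lambda v: v.pos)
    occupied: list[tuple[int, int]] = []
    for sv in sv_list:
        if sv.pos < 0 or sv.end > L:
            raise ValueError(f"SV at {sv.pos} outside region")
        if ancestral[sv.pos : sv.end] != sv.ref_allele:
            raise ValueError(f"SV ref allele mismatch at {sv.pos}")
        iv = (sv.pos, sv.end)
        if _overlaps(iv, occupied):
            raise ValueError(f"overlapping SVs at {sv.pos}")
        occupied.append(iv)

    rng = rng_for(seed, "haplotypes")
    truth: list[TruthVariant] = list(sv_list)

    # SNVs
    n_snv = rng.binomial(L, snv_rate)
    for pos in sorted(rng.choice(L, size=min(n_snv, L), replace=False)):
        pos = int(pos)
        if _overlaps((pos, pos + 1), occupied):
            continue
        ref = ancestral[pos]
        alt = BASES[(BASES.index(ref) + rng.integers(1, 4)) % 4]
        gt = "hap1" if rng.random() < 0.5 else "hap2"
        truth.append(TruthVariant(pos, ref, alt, gt))
        occupied.append((pos, pos + 1))

    # small indels: lengths geometric(p=0.5) clipped to 1..10 (< SV threshold)
    n_ind = rng.binomial(L, indel_rate)
    hi = max(L - 12, 1)
    for pos in sorted(rng.choice(hi, size=min(n_ind, hi), replace=False)):
        pos = int(pos)
        ln = int(min(rng.geometric(0.5), 10))
        is_del = rng.random() < 0.5
        gt = "hap1" if rng.random() < 0.5 else "hap2"
        if is_del:
            v = make_deletion(ancestral, pos, ln, gt)
        else:
            ins = "".join(rng.choice(list(BASES), size=ln))
            v = TruthVariant(pos, ancestral[pos], ancestral[pos] + ins, gt)
        iv = (v.pos, max(v.end, v.pos + 1))
        if _overlaps(iv, occupied):
            continue
        truth.append(v)
        occupied.append(iv)

    truth.sort(key=lambda v: v.pos)
    hap1 = apply_variants(ancestral, truth, "hap1")
    hap2 = apply_variants(ancestral, truth, "hap2")
    return hap1, hap2, truth


def apply_variants(ancestral: str, truth: list[TruthVariant], hap: str) -> str:
    """Apply the variants carried by haplotype `hap` ('hap1'|'hap2') in order."""
    parts: list[str] = []
    cur = 0
    for v in sorted(truth, key=lambda t: t.pos):
        if v.pos < cur:
            raise ValueError(f"overlapping variants at {v.pos}")
        if v.genotype == hap or v.genotype == "both":
            parts.append(ancestral[cur : v.pos])
            parts.append(v.alt_allele)
            cur = v.end
    parts.append(ancestral[cur:])
    return "".join(parts)


def haplotype_block_map(
    ancestral_length: int, truth: list[TruthVariant], hap: str
) -> list[tuple[int, int, int]]:
    """Colinear blocks (hap_start, hap_end, ref_start) mapping haplotype
    coordinates to ancestral coordinates; SNVs do not break blocks."""
    blocks: list[tuple[int, int, int]] = []
    ref = 0
    hp = 0
    for v in sorted(truth, key=lambda t: t.pos):
        if not (v.genotype == hap or v.genotype == "both"):
            continue
        if len(v.ref_allele) == len(v.alt_allele) == 1:
            continue  # SNV: coordinates unaffected
        span = v.pos - ref
        if span > 0:
            blocks.append((hp, hp + span, ref))
        hp += span + len(v.alt_allele)
        ref = v.end
    if ref < ancestral_length:
        blocks.append((hp, hp + ancestral_length - ref, ref))
    return blocks


def _apply_substitutions(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    arr = list(seq)
    for p in rng.choice(len(seq), size=min(n_err, len(seq)), replace=False):
        p = int(p)
        arr[p] = BASES[(BASES.index(arr[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def simulate_long_reads(
    hap: str,
    depth: float,
    mean_len: int = 10_000,
    len_sd: int = 1_000,
    error_rate: float = 0.0,
    seed: int = 0,
    hap_label: str = "hap1",
) -> list[SimulatedRead]:
    """Long reads (HiFi-like: size-selected lengths, very low error).

    Lengths are normal(mean_len, len_sd) truncated to [1 kb, 4x mean]; starts
    are uniform; only substitution errors are modelled.  Reads are emitted on
    the forward strand.  Generation stops once total bases reach
    depth * len(hap), so mean coverage is within one read length of target.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if mean_len < 1000:
        raise ValueError("mean_len must be at least 1000")
    rng = rng_for(seed, "long_reads")
    L = len(hap)
    target = depth * L
    reads: list[SimulatedRead] = []
    total = 0
    i = 0
    while total < target:
        ln = int(np.clip(rng.normal(mean_len, len_sd), 1000, 4 * mean_len))
        ln = min(ln, L)
        start = int(rng.integers(0, L - ln + 1))
        seq = _apply_substitutions(hap[start : start + ln], rng, error_rate)
        reads.append(
            SimulatedRead(
                id=f"{hap_label}_r{i:06d}",
                sequence=seq,
                truth_haplotype=hap_label,
                truth_interval=(start, start + ln),
                error_rate_applied=error_rate,
            )
        )
        total += ln
        i += 1
    return reads


def simulate_short_read_wgs(
    hap1: str,
    hap2: str,
    cn: CopyNumberSpec,
    depth_per_copy: float,
    read_len: int = 150,
    frag_mean: int = 400,
    frag_sd: int = 40,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[PairedRead]:
    """Copy-number-weighted paired short reads, uniform along each haplotype.

    The expected read-count ratio between haplotypes equals
    copies_hap1 : copies_hap2 — the signal the aneuploidy profiler recovers.
    """
    if read_len < 50:
        raise ValueError("read_len must be >= 50")
    rng = rng_for(seed, "short_reads")
    out: list[PairedRead] = []
    for hap, label, copies in ((hap1, "hap1", cn.copies_hap1), (hap2, "hap2", cn.copies_hap2)):
        if copies == 0 or depth_per_copy <= 0:
            continue
        L = len(hap)
        n_pairs = int(round(copies * depth_per_copy * L / (2 * read_len)))
        if n_pairs == 0:
            continue
        frags = np.clip(
            rng.normal(frag_mean, frag_sd, size=n_pairs), 2 * read_len, 1000
        ).astype(int)
        frags = np.minimum(frags, L)
        starts = (rng.random(n_pairs) * (L - frags + 1)).astype(int)
        for j in range(n_pairs):
            s, f = int(starts[j]), int(frags[j])
            r1 = hap[s : s + read_len]
            r2 = revcomp(hap[s + f - read_len : s + f])
            if error_rate > 0:
                r1 = _apply_substitutions(r1, rng, error_rate)
                r2 = _apply_substitutions(r2, rng, error_rate)
            out.append(
                PairedRead(
                    id=f"{label}_p{j:07d}",
                    seq1=r1,
                    seq2=r2,
                    truth_haplotype=label,
                    fragment=(s, s + f),
                )
            )
    return out


def truth_to_callset(truth: list[TruthVariant], phase_set: str = "ps0") -> list[PhasedVariant]:
    """Heterozygous truth variants as a phased callset (SVs and homozygous
    sites are not haplotagging signal and are excluded)."""
    out = []
    for v in truth:
        if v.genotype == "both" or v.vclass == "SV":
            continue
        h1 = v.alt_allele if v.genotype == "hap1" else v.ref_allele
        h2 = v.alt_allele if v.genotype == "hap2" else v.ref_allele
        out.append(
            PhasedVariant(v.pos, v.ref_allele, v.alt_allele, h1, h2, phase_set)
        )
    return out


def noisy_callset(
    truth: list[TruthVariant],
    ancestral: str,
    fn_frac: float = 0.02,
    fp_per_bp: float = 0.00002,
    seed: int = 0,
    stream: str = "callset_noise_a",
) -> list[PhasedVariant]:
    """A degraded copy of the truth callset emulating one caller's output:
    each true het site dropped with probability `fn_frac`, plus spurious het
    SNVs at `fp_per_bp`.  Two independently noised copies (different streams)
    stand in for the two sequencing platforms of the consensus step."""
    rng = rng_for(seed, stream)
    base = truth_to_callset(truth)
    occupied = {v.pos for v in base}
    kept = [v for v in base if rng.random() >= fn_frac]
    n_fp = rng.binomial(len(ancestral), fp_per_bp)
    for pos in rng.choice(len(ancestral), size=n_fp, replace=False):
        pos = int(pos)
        if pos in occupied:
            continue
        ref = ancestral[pos]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        if rng.random() < 0.5:
            kept.append(PhasedVariant(pos, ref, alt, alt, ref))
        else:
            kept.append(PhasedVariant(pos, ref, alt, ref, alt))
    return sorted(kept, key=lambda v: v.key)
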