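"""Read haplotagging and per-window longest-read downsampling.

Long reads are assigned to haplotypes by allele voting at consensus
heterozygous sites: each covered site where the read's sequence matches one
haplotype's allele (and not the other's) contributes one vote, the majority
wins, and ties or uninformative reads stay untagged.  Each partition is then
downsampled to a per-window target coverage by keeping the longest reads in
every fixed 10 kb window of the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import pandas as pd

from .locate import ReadLocator
from .phasing import PhasedVariant
from .simulate import SimulatedRead
from .util import revcomp


@dataclass(frozen=True)
class ReadAlignment:
    """A read's primary placement on the reference (0-based half-open)."""

    read_id: str
    sequence: str
    ref_start: int
    ref_end: int
    strand: str = "+"
    identity: float = 1.0

    @property
    def interval(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)


@dataclass(frozen=True)
class HaplotagResult:
    read_id: str
    assignment: str  # 'hap1' | 'hap2' | 'untagged'
    votes_hap1: int
    votes_hap2: int
    sites_covered: int


def align_reads(
    reads: Sequence[SimulatedRead],
    reference: str,
    min_span: float = 0.8,
    min_identity: float = 0.9,
    locator: ReadLocator | None = None,
) -> tuple[list[ReadAlignment], set[str]]:
    """Recruit reads against the reference.

    A read is recruited when its chained-anchor placement covers at least
    `min_span` of its length at `min_identity` within anchored segments.
    Reads dominated by reference-absent sequence (large novel insertions)
    fail the span floor and are left for the rescue stage.  Returns
    (alignments of recruited reads, ids of unrecruited reads).
    """
    loc = locator or ReadLocator(reference)
    alns: list[ReadAlignment] = []
    unaligned: set[str] = set()
    for r in reads:
        p = loc.locate(r.sequence)
        if p is None or p.span_frac < min_span or p.identity < min_identity:
            unaligned.add(r.id)
            continue
        alns.append(
            ReadAlignment(
                read_id=r.id,
                sequence=r.sequence,
                ref_start=p.t_start,
                ref_end=p.t_end,
                strand=p.strand,
                identity=p.identity,
            )
        )
    return alns, unaligned


def _allele_vote(
    seq: str, aln_start: int, v: PhasedVariant, reference: str, pad: int = 20
) -> str | None:
    """Which allele ('ref'/'alt') does the read carry at site v, or None.

    Decided by comparing edit distances of the two allele contexts (allele
    flanked by `pad` reference bases) against the read subsequence near the
    site; a tie is uninformative.
    """
    lo = max(0, v.pos - pad)
    hi = min(len(reference), v.pos + len(v.ref_allele) + pad)
    ctx_ref = reference[lo : v.pos] + v.ref_allele + reference[v.pos + len(v.ref_allele) : hi]
    ctx_alt = reference[lo : v.pos] + v.alt_allele + reference[v.pos + len(v.ref_allele) : hi]
    # generous window around the expected read offset: other het indels on the
    # read shift coordinates by a few bases across a long read
    slack = 100 + len(seq) // 50
    off = v.pos - aln_start
    w_lo = max(0, off - pad - slack)
    w_hi = min(len(seq), off + len(v.ref_allele) + pad + slack)
    window = seq[w_lo:w_hi]
    if len(window) < len(ctx_ref) // 2:
        return None
    d_ref = edlib.align(ctx_ref, window, mode="HW", task="distance")["editDistance"]
    d_alt = edlib.align(ctx_alt, window, mode="HW", task="distance")["editDistance"]
    if d_ref < d_alt:
        return "ref"
    if d_alt < d_ref:
        return "alt"
    return None


def haplotag_read(
    aln: ReadAlignment,
    variants: Sequence[PhasedVariant],
    reference: str,
) -> HaplotagResult:
    """Vote-based haplotype assignment of one aligned read."""
    seq = aln.sequence if aln.strand == "+" else revcomp(aln.sequence)
    v1 = v2 = covered = 0
    for v in variants:
        if v.pos < aln.ref_start or v.pos + len(v.ref_allele) > aln.ref_end:
            continue
        covered += 1
        allele = _allele_vote(seq, aln.ref_start, v, reference)
        if allele is None:
            continue
        carried = v.ref_allele if allele == "ref" else v.alt_allele
        if carried == v.hap1_allele:
            v1 += 1
        else:
            v2 += 1
    if covered == 0 or v1 == v2:
        assignment = "untagged"
    else:
        assignment = "hap1" if v1 > v2 else "hap2"
    return HaplotagResult(aln.read_id, assignment, v1, v2, covered)


def partition_reads(
    alignments: Sequence[ReadAlignment],
    variants: Sequence[PhasedVariant],
    reference: str,
) -> dict[str, set[str]]:
    """Split aligned reads into disjoint hap1 / hap2 / untagged id sets."""
    variants = sorted(variants, key=lambda v: v.pos)
    out: dict[str, set[str]] = {"hap1": set(), "hap2": set(), "untagged": set()}
    for aln in alignments:
        tag = haplotag_read(aln, variants, reference)
        out[tag.assignment].add(aln.read_id)
    return out


def downsample_longest_per_window(
    intervals: Iterable[tuple[str, int, int]],
    window_size: int = 10_000,
    target_cov: float = 30.0,
) -> set[str]:
    """Keep the longest reads per fixed window up to a target coverage.

    `intervals` are (read_id, ref_start, ref_end).  Windows are fixed
    non-overlapping tiles of the reference.  Within each window, overlapping
    reads are ranked by aligned length (descending, ties by id) and marked
    kept until the window's overlap bases first reach
    ``target_cov * window_size``; a read kept for any window is kept globally,
    preserving contiguity for assembly.  Idempotent.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    ivs = list(intervals)
    by_window: dict[int, list[tuple[str, int, int]]] = {}
    for rid, s, e in ivs:
        for w in range(s // window_size, (max(e, s + 1) - 1) // window_size + 1):
            by_window.setdefault(w, []).append((rid, s, e))
    kept: set[str] = set()
    budget = target_cov * window_size
    for w, members in sorted(by_window.items()):
        w_lo, w_hi = w * window_size, (w + 1) * window_size
        members.sort(key=lambda m: (-(m[2] - m[1]), m[0]))
        acc = 0.0
        for rid, s, e in members:
            if acc >= budget:
                break
            kept.add(rid)
            acc += min(e, w_hi) - max(s, w_lo)
    return kept


def window_coverage(
    intervals: Iterable[tuple[str, int, int]],
    region_length: int,
    window_size: int = 10_000,
) -> pd.DataFrame:
    """Per-window fold coverage table (BED-like: start, end, coverage)."""
    n = math.ceil(region_length / window_size)
    cov = [0.0] * n
    for _, s, e in intervals:
        for w in range(s // window_size, min((max(e, s + 1) - 1) // window_size, n - 1) + 1):
            w_lo, w_hi = w * window_size, min((w + 1) * window_size, region_length)
            cov[w] += max(0, min(e, w_hi) - max(s, w_lo)) / (w_hi - w_lo)
    return pd.DataFrame(
        {
            "start": [w * window_size for w in range(n)],
            "end": [min((w + 1) * window_size, region_length) for w in range(n)],
            "coverage": cov,
        }
    )
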