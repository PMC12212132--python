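"""Assembly-to-reference variant calling by unique-anchor chaining.

K-mers unique in both the assembled haplotype and the reference serve as
anchors; the longest colinear anchor chain defines exact-match alignment
blocks, and the gaps between blocks are decomposed into variants: small gaps
by end-to-end alignment into SNVs/indels, gaps with a net length difference
of at least 50 bp into structural variants (deletion or insertion of the net
size).  Chains spanning less than a minimum region length emit no calls,
mirroring the minimum-region constraint of assembly-based callers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import edlib
import pandas as pd

from .phasing import PhasedVariant, normalize_variant
from .util import revcomp

SV_MIN_SIZE = 50


@dataclass(frozen=True)
class AlignmentBlock:
    """An exact/high-identity co-linear block (both intervals half-open)."""

    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int

    @property
    def ref_interval(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)

    @property
    def qry_interval(self) -> tuple[int, int]:
        return (self.qry_start, self.qry_end)


@dataclass(frozen=True)
class AlignmentChain:
    blocks: tuple[AlignmentBlock, ...]
    strand: str  # '+' : qry coords on the haplotype; '-' : on its reverse complement
    ref_length: int
    qry_length: int

    @property
    def ref_span(self) -> int:
        return self.blocks[-1].ref_end - self.blocks[0].ref_start if self.blocks else 0


@dataclass(frozen=True)
class CalledVariant:
    ref_pos: int
    ref_allele: str
    alt_allele: str
    vclass: str  # 'SNV' | 'indel' | 'SV-DEL' | 'SV-INS'
    size: int
    haplotype: str = "hap1"

    @property
    def key(self):
        return (self.ref_pos, self.ref_allele, self.alt_allele)


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _lis_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of (ref, qry) anchors strictly increasing in both,
    via patience sorting on qry with pairs pre-sorted by ref."""
    import bisect

    tails: list[int] = []  # qry values of chain tails
    tails_idx: list[int] = []
    prev = [-1] * len(pairs)
    for i, (_, q) in enumerate(pairs):
        j = bisect.bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tails_idx.append(i)
        else:
            tails[j] = q
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i != -1:
        chain.append(pairs[i])
        i = prev[i]
    return chain[::-1]


def anchor_align(
    haplotype: str, reference_region: str, anchor_k: int = 31
) -> AlignmentChain:
    """Chain k-mers unique in both sequences into co-linear blocks.

    The strand with more shared unique anchors wins; for '-' the chain's
    query coordinates refer to the reverse complement of the haplotype.
    Raises when no anchors are found.
    """
    if len(haplotype) < anchor_k or len(reference_region) < anchor_k:
        raise ValueError("sequences shorter than anchor_k")
    ref_pos = _unique_kmer_positions(reference_region, anchor_k)

    def shared(qseq: str) -> list[tuple[int, int]]:
        qpos = _unique_kmer_positions(qseq, anchor_k)
        return sorted(
            (ref_pos[km], qpos[km]) for km in qpos.keys() & ref_pos.keys()
        )

    fwd = shared(haplotype)
    rc = revcomp(haplotype)
    rev = shared(rc) if len(fwd) < len(haplotype) // (2 * anchor_k) else []
    if len(rev) > len(fwd):
        strand, pairs, qseq = "-", rev, rc
    else:
        strand, pairs, qseq = "+", fwd, haplotype
    if not pairs:
        raise ValueError("no unique shared anchors between haplotype and reference")
    chain = _lis_chain(pairs)

    blocks: list[AlignmentBlock] = []
    rs, qs = chain[0]
    re_, qe = rs + anchor_k, qs + anchor_k
    for r, q in chain[1:]:
        if r - q == rs - qs and r <= re_:
            re_, qe = r + anchor_k, q + anchor_k  # overlapping same-offset anchor
        elif r >= re_ and q >= qe:
            blocks.append(AlignmentBlock(rs, re_, qs, qe))
            rs, qs, re_, qe = r, q, r + anchor_k, q + anchor_k
        # else: anchor conflicts with the running block boundary; drop it
    blocks.append(AlignmentBlock(rs, re_, qs, qe))
    return AlignmentChain(
        blocks=tuple(blocks),
        strand=strand,
        ref_length=len(reference_region),
        qry_length=len(haplotype),
    )


_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def _decompose_gap(
    reference: str, qseq: str, rs: int, re_: int, qs: int, qe: int
) -> list[tuple[int, str, str]]:
    """Small-gap decomposition into (pos, ref, alt) by end-space-free alignment."""
    ref_seg = reference[rs:re_]
    qry_seg = qseq[qs:qe]
    out: list[tuple[int, str, str]] = []
    if not ref_seg and not qry_seg:
        return out
    if not ref_seg:  # pure insertion, anchored on the previous reference base
        out.append((rs - 1, reference[rs - 1], reference[rs - 1] + qry_seg))
        return out
    if not qry_seg:  # pure deletion
        out.append((rs - 1, reference[rs - 1 : re_], reference[rs - 1]))
        return out
    cig = edlib.align(qry_seg, ref_seg, mode="NW", task="path")["cigar"]
    rp, qp = rs, qs
    for n, op in _CIG_RE.findall(cig):
        n = int(n)
        if op in ("=", "M"):
            rp += n
            qp += n
        elif op == "X":
            for t in range(n):
                out.append((rp + t, reference[rp + t], qseq[qp + t]))
            rp += n
            qp += n
        elif op == "I":  # present in query only
            out.append((rp - 1, reference[rp - 1], reference[rp - 1] + qseq[qp : qp + n]))
            qp += n
        elif op == "D":  # present in reference only
            out.append((rp - 1, reference[rp - 1 : rp + n], reference[rp - 1]))
            rp += n
    return out


def _classify(ref: str, alt: str) -> tuple[str, int]:
    size = abs(len(alt) - len(ref))
    if size == 0:
        return ("SNV" if len(ref) == 1 else "MNV"), 0
    if size >= SV_MIN_SIZE:
        return ("SV-DEL" if len(ref) > len(alt) else "SV-INS"), size
    return "indel", size


def call_variants(
    chain: AlignmentChain,
    haplotype: str,
    reference_region: str,
    min_region: int = 10_000,
    haplotype_label: str = "hap1",
) -> list[CalledVariant]:
    """Decompose inter-block gaps of a chain into normalized variant calls.

    Gaps where both sides are < 50 bp (or whose net difference is < 50 bp)
    are aligned end-to-end and split into SNVs and indels; a net difference
    >= 50 bp is a structural deletion/insertion of the net size; gaps >= 50 bp
    on both sides with a large net difference are emitted as a DEL+INS pair
    (breakend-free representation of a complex replacement).
    """
    if chain.ref_span < min_region:
        return []
    qseq = haplotype if chain.strand == "+" else revcomp(haplotype)
    raw: list[tuple[int, str, str]] = []
    for b1, b2 in zip(chain.blocks, chain.blocks[1:]):
        rg = b2.ref_start - b1.ref_end
        qg = b2.qry_start - b1.qry_end
        if rg == 0 and qg == 0:
            continue
        net = abs(rg - qg)
        if (rg < SV_MIN_SIZE and qg < SV_MIN_SIZE) or net < SV_MIN_SIZE:
            raw.extend(
                _decompose_gap(
                    reference_region, qseq, b1.ref_end, b2.ref_start, b1.qry_end, b2.qry_start
                )
            )
        elif rg >= SV_MIN_SIZE and qg >= SV_MIN_SIZE:
            pos = b1.ref_end - 1
            raw.append((pos, reference_region[pos : b2.ref_start], reference_region[pos]))
            raw.append((pos, reference_region[pos], reference_region[pos] + qseq[b1.qry_end : b2.qry_start]))
        else:
            pos = b1.ref_end - 1
            raw.append(
                (
                    pos,
                    reference_region[pos : b2.ref_start],
                    reference_region[pos] + qseq[b1.qry_end : b2.qry_start],
                )
            )
    calls: list[CalledVariant] = []
    seen: set = set()
    for pos, ref, alt in raw:
        if ref == alt:
            continue
        pv = PhasedVariant(pos, ref, alt, alt, ref)
        pv = normalize_variant(pv, reference_region)
        key = (pv.pos, pv.ref_allele, pv.alt_allele)
        if key in seen:
            continue
        seen.add(key)
        vclass, size = _classify(pv.ref_allele, pv.alt_allele)
        calls.append(
            CalledVariant(
                ref_pos=pv.pos,
                ref_allele=pv.ref_allele,
                alt_allele=pv.alt_allele,
                vclass=vclass,
                size=size,
                haplotype=haplotype_label,
            )
        )
    return sorted(calls, key=lambda c: c.key)


def variant_summary(
    calls_by_hap: dict[str, Sequence[CalledVariant]],
    region_length: int,
    window: int = 100_000,
) -> pd.DataFrame:
    """Per-window, per-class variant counts (window rows x class columns),
    summed over haplotypes; total conserves the number of calls."""
    n = -(-region_length // window)
    classes = ["SNV", "MNV", "indel", "SV-DEL", "SV-INS"]
    rows = {c: [0] * n for c in classes}
    for calls in calls_by_hap.values():
        for c in calls:
            w = min(c.ref_pos // window, n - 1)
            rows[c.vclass][w] += 1
    df = pd.DataFrame(rows)
    df.insert(0, "window_start", [w * window for w in range(n)])
    return df
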