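"""Two-round targeted assembly with short-contig filtering and read rescue.

The assembler is a deliberately minimal greedy overlap-layout stand-in for a
production long-read assembler: exact k-mer seeds locate candidate overlaps
against the growing contig, candidates are verified by banded edit distance,
and the contig is extended by the read with the largest overhang.  It is
adequate for low-error, well-covered targeted data, which is the regime this
pipeline simulates; an external assembler can be substituted through the
``assembler`` hook of :func:`assemble_haplotype`.

Round structure mirrors the targeted workflow: assemble the haplotype
partition (merged with untagged reads), drop contigs shorter than 50 kb,
realign all reads to the preliminary contigs to rescue those that were never
recruited to the reference, and re-assemble with the rescued reads included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import edlib

from .locate import ReadLocator

MIN_CONTIG_LEN = 50_000  # preliminary contigs shorter than this are excluded


@dataclass
class Contig:
    id: str
    sequence: str
    round: int = 1
    member_reads: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    haplotype: str
    contigs: list[Contig]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    @property
    def largest(self) -> int:
        return max((c.length for c in self.contigs), default=0)


def _verify(a: str, b: str, max_frac: float) -> bool:
    if a == b:
        return True
    limit = int(max_frac * max(len(a), len(b))) + 1
    d = edlib.align(a, b, mode="NW", task="distance", k=limit)["editDistance"]
    return d != -1 and d <= max_frac * max(len(a), len(b))


class _ReadIndex:
    """Sampled k-mer index over a read set for overlap candidate lookup."""

    def __init__(self, reads: Sequence[tuple[str, str]], k: int, step: int):
        self.k = k
        self.step = step
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ridx, (_, seq) in enumerate(reads):
            positions = list(range(0, max(len(seq) - k, 0) + 1, step))
            for q in positions:
                self.index.setdefault(seq[q : q + k], []).append((ridx, q))


def greedy_olc_assemble(
    reads: Sequence[tuple[str, str]],
    min_overlap: int = 2_000,
    max_mismatch_frac: float = 0.01,
    k: int = 21,
) -> list[Contig]:
    """Greedy best-overlap assembly of (id, sequence) reads.

    Deterministic: seeds are taken longest-first (ties by id), and at each
    extension the verified candidate with the largest overhang (ties by id)
    wins.  Each read contributes to at most one contig; reads contained in a
    finished contig are absorbed as members.
    """
    if min_overlap < 500:
        raise ValueError("min_overlap must be >= 500")
    order = sorted(range(len(reads)), key=lambda i: (-len(reads[i][1]), reads[i][0]))
    reads = list(reads)
    step = max(1, min(256, min_overlap - k))
    ridx = _ReadIndex(reads, k, step)
    used = [False] * len(reads)
    max_rlen = max((len(s) for _, s in reads), default=0)
    contigs: list[Contig] = []

    def candidates_at(contig: str, lo: int, hi: int) -> dict[tuple[int, int], int]:
        cand: dict[tuple[int, int], int] = {}
        for p in range(lo, min(hi, len(contig) - k + 1)):
            for r, q in ridx.index.get(contig[p : p + k], ()):
                if not used[r]:
                    key = (r, p - q)  # read start offset in contig coords
                    cand[key] = cand.get(key, 0) + 1
        return cand

    def try_extend(contig: str, members: list[str], side: str) -> str | None:
        if side == "right":
            lo = max(0, len(contig) - max_rlen)
            hi = len(contig)
        else:
            lo, hi = 0, min(len(contig), max_rlen)
        cand = candidates_at(contig, lo, hi)
        scored = []
        for (r, off), _ in cand.items():
            rlen = len(reads[r][1])
            if side == "right":
                overhang = off + rlen - len(contig)
                overlap = len(contig) - off
                if overhang <= 0 or off < 0 or overlap < min_overlap:
                    continue
            else:
                overhang = -off
                overlap = off + rlen
                if overhang <= 0 or overlap < min_overlap or overlap > len(contig):
                    continue
            scored.append((overhang, reads[r][0], r, off, overlap))
        for overhang, _, r, off, overlap in sorted(scored, key=lambda t: (-t[0], t[1])):
            seq = reads[r][1]
            if side == "right":
                ok = _verify(seq[:overlap], contig[off:], max_mismatch_frac)
                if ok:
                    used[r] = True
                    members.append(reads[r][0])
                    return contig + seq[overlap:]
            else:
                ok = _verify(seq[-overlap:], contig[:overlap], max_mismatch_frac)
                if ok:
                    used[r] = True
                    members.append(reads[r][0])
                    return seq[:-overlap] + contig

        return None

    def absorb_contained(contig: str, members: list[str]) -> None:
        # full-position index over the finished contig; sampled read k-mers
        # vote an offset, then the whole read is verified at that offset
        cidx: dict[str, int] = {}
        for p in range(len(contig) - k + 1):
            cidx.setdefault(contig[p : p + k], p)
        for r in range(len(reads)):
            if used[r]:
                continue
            seq = reads[r][1]
            offs: dict[int, int] = {}
            for q in range(0, max(len(seq) - k, 0) + 1, step):
                p = cidx.get(seq[q : q + k])
                if p is not None:
                    offs[p - q] = offs.get(p - q, 0) + 1
            if not offs:
                continue
            off = max(offs, key=lambda o: (offs[o], -o))
            if off >= 0 and off + len(seq) <= len(contig):
                if _verify(seq, contig[off : off + len(seq)], max_mismatch_frac):
                    used[r] = True
                    members.append(reads[r][0])

    n_ctg = 0
    for i in order:
        if used[i]:
            continue
        used[i] = True
        members = [reads[i][0]]
        contig = reads[i][1]
        grown = True
        while grown:
            grown = False
            for side in ("right", "left"):
                ext = try_extend(contig, members, side)
                if ext is not None:
                    contig = ext
                    grown = True
        absorb_contained(contig, members)
        contigs.append(
            Contig(id=f"ctg{n_ctg:04d}", sequence=contig, member_reads=sorted(members))
        )
        n_ctg += 1
    return contigs


def filter_contigs(contigs: Iterable[Contig], min_len: int = MIN_CONTIG_LEN) -> list[Contig]:
    """Drop contigs shorter than `min_len` (order preserved)."""
    return [c for c in contigs if c.length >= min_len]


def rescue_supplementary_reads(
    all_reads: Sequence[tuple[str, str]],
    preliminary: Sequence[Contig],
    reference_aligned_ids: set[str],
    min_identity: float = 0.95,
    min_span: float = 0.8,
) -> set[str]:
    """Ids of reads absent from the original recruitment that align to the
    preliminary assembly (identity >= min_identity over >= min_span of the
    read).  Disjoint from `reference_aligned_ids` by construction."""
    if not preliminary:
        raise ValueError("preliminary assembly is empty")
    pool = [(rid, seq) for rid, seq in all_reads if rid not in reference_aligned_ids]
    if not pool:
        return set()
    locators = [ReadLocator(c.sequence) for c in preliminary]
    rescued: set[str] = set()
    for rid, seq in pool:
        for loc in locators:
            p = loc.locate(seq)
            if p is not None and p.identity >= min_identity and p.span_frac >= min_span:
                rescued.add(rid)
                break
    return rescued


def assemble_haplotype(
    round1_reads: Sequence[tuple[str, str]],
    all_reads: Sequence[tuple[str, str]],
    reference_aligned_ids: set[str],
    haplotype: str = "hap1",
    min_overlap: int = 2_000,
    max_mismatch_frac: float = 0.01,
    min_contig_len: int = MIN_CONTIG_LEN,
    assembler: Callable[..., list[Contig]] | None = None,
) -> tuple[Assembly, dict]:
    """Two-round assembly of one haplotype.

    Round 1 assembles the (already downsampled) partition reads and filters
    short contigs; unrecruited reads that align to the preliminary contigs
    are rescued and a second round re-assembles the union.  When nothing is
    rescued the round-1 result is returned unchanged.  Returns the final
    Assembly plus a stage-count report.
    """
    if not round1_reads:
        raise ValueError("no reads to assemble")
    asm = assembler or greedy_olc_assemble
    round1 = asm(round1_reads, min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac)
    prelim = filter_contigs(round1, min_contig_len)
    info = {
        "round1_contigs": len(round1),
        "round1_filtered_contigs": len(prelim),
        "round1_total_length": sum(c.length for c in prelim),
    }
    rescued: set[str] = set()
    if prelim:
        rescued = rescue_supplementary_reads(all_reads, prelim, reference_aligned_ids)
    info["rescued_reads"] = len(rescued)
    if not rescued:
        final = prelim if prelim else round1
        for c in final:
            c.round = 1
        info["round2_total_length"] = sum(c.length for c in final)
        return Assembly(haplotype=haplotype, contigs=final), info
    have = {rid for rid, _ in round1_reads}
    by_id = dict(all_reads)
    round2_reads = list(round1_reads) + [
        (rid, by_id[rid]) for rid in sorted(rescued) if rid not in have
    ]
    round2 = asm(round2_reads, min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac)
    final = filter_contigs(round2, min_contig_len) or round2
    for c in final:
        c.round = 2
    info["round2_total_length"] = sum(c.length for c in final)
    return Assembly(haplotype=haplotype, contigs=final), info
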