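"""Assembly evaluation mathematics.

Collision-aware optimal k-mer size, k-mer completeness and consensus quality
value (QV), NGA50/LGA50, duplication ratio and reference coverage.  The
k-mer machinery follows the standard reference-free evaluation model: read
k-mers seen at least twice are "reliable" (singletons are dominated by
sequencing errors); completeness is the fraction of reliable read k-mers
found in the assembly; assembly k-mers unsupported by any read k-mer imply a
per-base consensus error rate E = 1 - (1 - b/T)^(1/k) reported as
QV = -10*log10(E).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .util import canonical


def optimal_k(region_length: int, collision_rate: float = 0.001) -> tuple[float, int]:
    """Smallest k at which random k-mer collisions over a region of the given
    length stay below `collision_rate`:  k = log4(L * (1 - e) / e).

    Returns (k to two decimals, round(k) as the practical counting k).
    """
    if region_length < 1:
        raise ValueError("region_length must be >= 1")
    if not 0.0 < collision_rate < 1.0:
        raise ValueError("collision_rate must lie in (0, 1)")
    k = math.log(region_length * (1.0 - collision_rate) / collision_rate, 4.0)
    return round(k, 2), round(k)


@dataclass(frozen=True)
class KmerStats:
    k: int
    read_kmers_total: int  # distinct canonical read k-mers
    read_kmers_reliable: int  # distinct, multiplicity >= 2
    asm_kmers_total: int  # assembly k-mer positions (with multiplicity)
    asm_only_kmers: int  # positions whose k-mer has no read support
    shared_reliable: int  # reliable read k-mers present in the assembly

    def __post_init__(self):
        if self.shared_reliable > self.read_kmers_reliable:
            raise ValueError("shared_reliable exceeds read_kmers_reliable")
        if self.asm_only_kmers > self.asm_kmers_total:
            raise ValueError("asm_only_kmers exceeds asm_kmers_total")


def kmer_counts(seqs: Iterable[str], k: int) -> Counter:
    """Canonical k-mer multiplicity counter over a set of sequences."""
    c: Counter = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            c[canonical(seq[i : i + k])] += 1
    return c


_BASE_CODE = np.zeros(256, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _c


def canonical_kmer_array(seq: str, k: int) -> np.ndarray:
    """Canonical k-mers of `seq` as 2-bit-packed integers, one per position.

    Vectorized equivalent of ``canonical(seq[i:i+k])`` for every i; requires
    k <= 31 so a k-mer fits in a uint64.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for packed representation")
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    a = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.uint64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | a[j : m + j]
    comp = (np.uint64(3) - a)[::-1]
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        rev = (rev << np.uint64(2)) | comp[j : m + j]
    return np.minimum(fwd, rev[::-1])


def _packed_multiset(seqs: Iterable[str], k: int) -> np.ndarray:
    parts = [canonical_kmer_array(s, k) for s in seqs]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.concatenate(parts)


def compute_kmer_stats(
    read_seqs: Iterable[str],
    asm_seqs: Iterable[str],
    k: int,
    min_reliable_mult: int = 2,
    hap_specific: Iterable[str] | None = None,
) -> KmerStats:
    """Tabulate read/assembly k-mer sharing.

    `hap_specific` optionally restricts the completeness denominator to a
    given k-mer set (e.g. haplotype-specific k-mers); by default all reliable
    read k-mers are used.
    """
    read_all = _packed_multiset(read_seqs, k)
    asm_all = _packed_multiset(asm_seqs, k)
    read_uniq, read_mult = np.unique(read_all, return_counts=True)
    reliable = read_uniq[read_mult >= min_reliable_mult]
    if hap_specific is not None:
        restrict = np.unique(
            np.concatenate([canonical_kmer_array(s, k) for s in hap_specific])
            if not isinstance(hap_specific, np.ndarray)
            else hap_specific
        )
        reliable = reliable[np.isin(reliable, restrict)]
    asm_uniq, asm_mult = np.unique(asm_all, return_counts=True)
    asm_only = int(asm_mult[~np.isin(asm_uniq, read_uniq)].sum())
    shared = int(np.isin(reliable, asm_uniq).sum())
    return KmerStats(
        k=k,
        read_kmers_total=int(len(read_uniq)),
        read_kmers_reliable=int(len(reliable)),
        asm_kmers_total=int(len(asm_all)),
        asm_only_kmers=asm_only,
        shared_reliable=shared,
    )


def kmer_completeness(stats: KmerStats) -> float:
    """Fraction of reliable read k-mers recovered by the assembly."""
    if stats.read_kmers_reliable == 0:
        raise ValueError("no reliable read k-mers")
    return stats.shared_reliable / stats.read_kmers_reliable


QV_CAP = 99.0


def consensus_qv(stats: KmerStats, cap: float = QV_CAP) -> float:
    """Phred-scaled consensus accuracy from unsupported assembly k-mers."""
    if stats.asm_kmers_total <= 0:
        raise ValueError("empty assembly k-mer set")
    if stats.asm_only_kmers == 0:
        return cap
    err = 1.0 - (1.0 - stats.asm_only_kmers / stats.asm_kmers_total) ** (1.0 / stats.k)
    return min(cap, -10.0 * math.log10(err))


def _block_ref_len(b) -> int:
    return b.ref_end - b.ref_start


def _block_qry_len(b) -> int:
    return b.qry_end - b.qry_start


def nga50(blocks: Sequence, reference_length: int) -> tuple[int, int]:
    """(NGA50, LGA50): the aligned-block length at which blocks of that
    length or longer first cover >= half the reference, and its rank.
    (0, 0) when half-coverage is never reached."""
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    lengths = sorted((_block_ref_len(b) for b in blocks), reverse=True)
    acc = 0
    for rank, ln in enumerate(lengths, start=1):
        acc += ln
        if acc >= reference_length / 2:
            return ln, rank
    return 0, 0


def _union_bases(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def coverage_fraction(blocks: Sequence, reference_length: int) -> float:
    """Union-covered reference bases over reference length."""
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    return _union_bases((b.ref_start, b.ref_end) for b in blocks) / reference_length


def duplication_ratio(blocks: Sequence, reference_length: int) -> float:
    """Total aligned query bases per covered reference base (>= 1 when any
    coverage exists; 0.0 for an empty block set)."""
    covered = _union_bases((b.ref_start, b.ref_end) for b in blocks)
    if covered == 0:
        return 0.0
    return sum(_block_qry_len(b) for b in blocks) / covered
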