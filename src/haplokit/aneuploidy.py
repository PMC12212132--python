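"""Personal-reference copy-ratio (aneuploidy) profiling.

The target interval of the reference is replaced by each assembled haplotype
to form a two-sequence personal reference.  Short reads matching one
haplotype exactly and the other not at all ("unique zero-edit" reads) give
per-base depth on each haplotype; depth is lifted over to reference
coordinates through the haplotype-to-reference alignment chain; at every
position carrying a variant between the haplotypes the depth ratio is log2-
transformed and smoothed over fixed 10 kb windows, with variant-free windows
gap-filled from their nearest computed neighbour.  The overall ratio (the
dashed line of a copy-ratio plot) is 2 to the median per-window log2 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .simulate import PairedRead
from .util import revcomp
from .variants import AlignmentChain


@dataclass(frozen=True)
class PersonalReference:
    """Reference with the target interval excised and one haplotype embedded,
    once per haplotype."""

    seq_hap1: str
    seq_hap2: str
    interval: tuple[int, int]  # excised interval, reference coordinates
    hap_lengths: tuple[int, int]

    def embedded_interval(self, hap: int) -> tuple[int, int]:
        """Interval occupied by the embedded haplotype in personal sequence hap (1|2)."""
        s = self.interval[0]
        return (s, s + self.hap_lengths[hap - 1])


def build_personal_reference(
    reference: str, interval: tuple[int, int], hap1: str, hap2: str
) -> PersonalReference:
    s, e = interval
    if not (0 <= s < e <= len(reference)):
        raise ValueError("interval out of bounds or empty")
    if not hap1 or not hap2:
        raise ValueError("haplotypes must be non-empty")
    return PersonalReference(
        seq_hap1=reference[:s] + hap1 + reference[e:],
        seq_hap2=reference[:s] + hap2 + reference[e:],
        interval=(s, e),
        hap_lengths=(len(hap1), len(hap2)),
    )


class ExactMatcher:
    """Zero-edit read placement by k-mer lookup plus literal comparison."""

    def __init__(self, target: str, k: int = 31):
        self.target = target
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(target) - k + 1):
            hits = index.setdefault(target[i : i + k], [])
            if len(hits) < 50:
                hits.append(i)
        self.index = index

    def _match_oriented(self, read: str) -> tuple[int, int] | None:
        if len(read) < self.k:
            p = self.target.find(read)
            return (p, p + len(read)) if p >= 0 else None
        for p in self.index.get(read[: self.k], ()):
            if self.target[p : p + len(read)] == read:
                return (p, p + len(read))
        return None

    def match(self, read: str) -> tuple[int, int] | None:
        """Half-open interval of an exact occurrence (either strand), or None."""
        hit = self._match_oriented(read)
        if hit is None:
            hit = self._match_oriented(revcomp(read))
        return hit


def unique_zero_edit_filter(
    alignments_to_hap1: dict[str, tuple[int, int] | None],
    alignments_to_hap2: dict[str, tuple[int, int] | None],
) -> tuple[dict[str, tuple[int, int]], dict[str, tuple[int, int]]]:
    """Keep a read for haplotype i iff it has a zero-edit placement on
    haplotype i and none on the other; everything else is dropped.

    Inputs map read id -> zero-edit interval or None (no zero-edit match).
    """
    kept1: dict[str, tuple[int, int]] = {}
    kept2: dict[str, tuple[int, int]] = {}
    for rid in alignments_to_hap1.keys() | alignments_to_hap2.keys():
        a1 = alignments_to_hap1.get(rid)
        a2 = alignments_to_hap2.get(rid)
        if a1 is not None and a2 is None:
            kept1[rid] = a1
        elif a2 is not None and a1 is None:
            kept2[rid] = a2
    return kept1, kept2


def match_reads(
    pairs: Iterable[PairedRead], personal_seq: str, k: int = 31
) -> dict[str, tuple[int, int] | None]:
    """Zero-edit placements of both mates of every pair on one personal
    sequence (mates are treated as independent reads, ids suffixed /1, /2)."""
    m = ExactMatcher(personal_seq, k=k)
    out: dict[str, tuple[int, int] | None] = {}
    for p in pairs:
        out[p.id + "/1"] = m.match(p.seq1)
        out[p.id + "/2"] = m.match(p.seq2)
    return out


def depth_profile(placements: Iterable[tuple[int, int]], length: int) -> np.ndarray:
    """Per-base depth vector from half-open placement intervals."""
    d = np.zeros(length + 1, dtype=np.int64)
    for s, e in placements:
        d[max(s, 0)] += 1
        d[min(e, length)] -= 1
    return np.cumsum(d[:-1]).astype(float)


def project_depth(depth: np.ndarray, chain: AlignmentChain) -> np.ndarray:
    """Lift per-base haplotype depth to reference coordinates through a chain.

    Block interiors map 1:1.  Between blocks, min(ref_gap, qry_gap) bases are
    mapped 1:1 from the left (covering substitution gaps); remaining
    reference-only positions (deletions on the haplotype) are NaN, and
    haplotype-only positions (insertions) are dropped.
    """
    if not chain.blocks:
        raise ValueError("empty alignment chain")
    out = np.full(chain.ref_length, np.nan)
    for b in chain.blocks:
        out[b.ref_start : b.ref_end] = depth[b.qry_start : b.qry_end]
    for b1, b2 in zip(chain.blocks, chain.blocks[1:]):
        rg = b2.ref_start - b1.ref_end
        qg = b2.qry_start - b1.qry_end
        m = min(rg, qg)
        if m > 0:
            out[b1.ref_end : b1.ref_end + m] = depth[b1.qry_end : b1.qry_end + m]
    return out


@dataclass(frozen=True)
class CopyRatioProfile:
    window_size: int
    window_starts: np.ndarray
    log2_ratio: np.ndarray
    gap_filled: np.ndarray  # True where no variant position contributed
    overall_ratio: float


def log2_ratio_profile(
    depth1_ref: np.ndarray,
    depth2_ref: np.ndarray,
    variant_positions: Sequence[int],
    window: int = 10_000,
    eps: float = 0.5,
    use_mean: bool = False,
    log_first: bool = True,
) -> CopyRatioProfile:
    """Windowed log2 depth-ratio profile in reference coordinates.

    At each variant position with defined depth on both haplotypes the ratio
    r = (d1 + eps)/(d2 + eps) is computed; each fixed window takes the mean
    of log2 r over its variant positions (per-position log transform first,
    then smoothing — with eps = 0.5 the concavity of the log and the
    pseudo-depth offset cancel almost exactly under Poisson depth, so the
    estimator is close to unbiased; ``log_first=False`` takes log2 of the
    mean ratio instead).  Windows without variant positions are filled from
    the nearest computed window (ties resolved leftward).  The overall ratio
    is 2**median of the per-window values; `use_mean` swaps in the mean.
    """
    L = len(depth1_ref)
    if len(depth2_ref) != L:
        raise ValueError("depth tracks differ in length")
    vp = [
        p
        for p in sorted(set(int(p) for p in variant_positions))
        if 0 <= p < L and np.isfinite(depth1_ref[p]) and np.isfinite(depth2_ref[p])
    ]
    if not vp:
        raise ValueError("no variant positions with defined depth on both haplotypes")
    n = -(-L // window)
    vals = np.full(n, np.nan)
    ratios: dict[int, list[float]] = {}
    for p in vp:
        r = (depth1_ref[p] + eps) / (depth2_ref[p] + eps)
        ratios.setdefault(p // window, []).append(r)
    for w, rs in ratios.items():
        if log_first:
            vals[w] = float(np.mean(np.log2(rs)))
        else:
            vals[w] = float(np.log2(np.mean(rs)))
    computed = np.where(np.isfinite(vals))[0]
    gap_filled = ~np.isfinite(vals)
    for w in np.where(gap_filled)[0]:
        j = np.searchsorted(computed, w)
        left = computed[j - 1] if j > 0 else None
        right = computed[j] if j < len(computed) else None
        if left is None:
            vals[w] = vals[right]
        elif right is None or (w - left) <= (right - w):
            vals[w] = vals[left]
        else:
            vals[w] = vals[right]
    agg = np.mean if use_mean else np.median
    overall = float(2.0 ** agg(vals))
    return CopyRatioProfile(
        window_size=window,
        window_starts=np.arange(n) * window,
        log2_ratio=vals,
        gap_filled=gap_filled,
        overall_ratio=overall,
    )


def mhc_alignment_gain(reads_reference_region: int, reads_personal_region: int) -> float:
    """Percent gain in region-aligned reads from using the personal reference."""
    if reads_reference_region <= 0:
        raise ValueError("reference-region read count must be positive")
    return 100.0 * (reads_personal_region - reads_reference_region) / reads_reference_region


def plot_profile(profile: CopyRatioProfile, path, genes: list[tuple[int, int, str]] | None = None):
    """Copy-ratio figure: per-window log2 track, dashed overall-ratio line,
    optional gene boxes along the x axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    x = profile.window_starts / 1e3
    ax.plot(x, profile.log2_ratio, color="tab:orange", lw=1.5, label="10 kb window")
    overall = np.log2(profile.overall_ratio)
    ax.axhline(overall, ls="--", color="k", lw=1, label=f"overall {profile.overall_ratio:.2f}")
    ax.axhline(0.0, color="grey", lw=0.5)
    if genes:
        for s, e, name in genes:
            ax.axvspan(s / 1e3, e / 1e3, color="tab:blue", alpha=0.15)
            ax.text((s + e) / 2e3, ax.get_ylim()[0], name, ha="center", fontsize=6)
    ax.set_xlabel("reference position (kb)")
    ax.set_ylabel("log2 depth ratio")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
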