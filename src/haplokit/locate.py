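"""Seeded read placement against a target sequence.

A light-weight, minimap2-flavoured locator: exact k-mer anchors sampled along
the query are chained colinearly (tolerating large indel offset shifts, so a
read spanning a kilobase-scale deletion still places as one alignment), and
per-segment edit distances from edlib yield an identity over the anchored
span.  Used for initial read recruitment to the reference, supplementary-read
rescue against preliminary contigs, and assigning reference intervals for
windowed downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .util import revcomp


@dataclass(frozen=True)
class Placement:
    """Best chained placement of a query on the target."""

    t_start: int
    t_end: int
    q_start: int
    q_end: int
    strand: str
    identity: float  # 1 - edits/anchored-span, SV jumps not penalized
    span_frac: float  # anchored query bases / query length
    edit_distance: int
    n_anchors: int


class ReadLocator:
    """Exact k-mer index over a target with chained-anchor query placement."""

    def __init__(self, target: str, k: int = 21, max_hits: int = 8):
        self.target = target
        self.k = k
        self.max_hits = max_hits
        index: dict[str, list[int]] = {}
        for i in range(len(target) - k + 1):
            kmer = target[i : i + k]
            hits = index.setdefault(kmer, [])
            if len(hits) <= max_hits:  # over-full entries are repeat-masked
                hits.append(i)
        self.index = {km: h for km, h in index.items() if len(h) <= max_hits}

    def _anchors(self, seq: str, step: int) -> list[tuple[int, int]]:
        k = self.k
        if len(seq) < k:
            return []
        qpos = list(range(0, len(seq) - k + 1, step))
        if qpos[-1] != len(seq) - k:
            qpos.append(len(seq) - k)
        pairs: list[tuple[int, int]] = []
        for q in qpos:
            for t in self.index.get(seq[q : q + k], ()):
                pairs.append((q, t))
        return sorted(pairs)

    def _chain(
        self, pairs: list[tuple[int, int]], max_shift: int
    ) -> list[tuple[int, int]]:
        # O(n^2) DP maximizing anchor count under colinearity; n is small
        # because anchors are sampled sparsely along the query.
        n = len(pairs)
        best = [1] * n
        prev = [-1] * n
        for i in range(n):
            qi, ti = pairs[i]
            for j in range(i):
                qj, tj = pairs[j]
                if qj < qi and tj < ti and abs((ti - tj) - (qi - qj)) <= max_shift:
                    if best[j] + 1 > best[i]:
                        best[i] = best[j] + 1
                        prev[i] = j
        if n == 0:
            return []
        end = max(range(n), key=lambda i: (best[i], -pairs[i][0]))
        chain = []
        while end != -1:
            chain.append(pairs[end])
            end = prev[end]
        return chain[::-1]

    def _score(self, seq: str, chain: list[tuple[int, int]]) -> tuple[int, int, float]:
        """Segment the chain at large offset shifts (structural gaps) and sum
        per-segment edit distances.  Returns (span_bases, edits, identity)."""
        k = self.k
        segments: list[list[tuple[int, int]]] = [[chain[0]]]
        for a in chain[1:]:
            pq, pt = segments[-1][-1]
            if abs((a[1] - pt) - (a[0] - pq)) > 50:
                segments.append([a])
            else:
                segments[-1].append(a)
        span = 0
        edits = 0
        for seg in segments:
            qa, ta = seg[0]
            qb, tb = seg[-1]
            qs = seq[qa : qb + k]
            ts = self.target[ta : tb + k]
            span += len(qs)
            if qs != ts:
                edits += edlib.align(qs, ts, mode="NW", task="distance")["editDistance"]
        identity = 1.0 - edits / span if span else 0.0
        return span, edits, identity

    def locate(
        self,
        seq: str,
        step: int = 200,
        max_shift: int = 50_000,
        min_anchors: int = 2,
        both_strands: bool = True,
    ) -> Placement | None:
        """Best placement of `seq`, or None if it cannot be anchored."""
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            pairs = self._anchors(s, step)
            if len(pairs) > 400:  # repeat blow-up guard: keep unique-hit anchors
                seen: dict[int, list[int]] = {}
                for q, t in pairs:
                    seen.setdefault(q, []).append(t)
                pairs = sorted((q, ts[0]) for q, ts in seen.items() if len(ts) == 1)
            chain = self._chain(pairs, max_shift)
            if len(chain) < min_anchors:
                if not both_strands:
                    break
                continue
            span, edits, identity = self._score(s, chain)
            qa, ta = chain[0]
            qb, tb = chain[-1]
            return Placement(
                t_start=ta,
                t_end=tb + self.k,
                q_start=qa,
                q_end=qb + self.k,
                strand=strand,
                identity=identity,
                span_frac=span / len(seq),
                edit_distance=edits,
                n_anchors=len(chain),
            )
        return None
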