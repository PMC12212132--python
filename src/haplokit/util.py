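"""Small shared helpers: reverse complement, k-mer iteration, seeded RNGs."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Canonical form of a k-mer: lexicographic min of forward and reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int):
    """Yield (position, k-mer) over every position of `seq`."""
    for i in range(len(seq) - k + 1):
        yield i, seq[i : i + k]


# Fixed per-operation stream codes: one RNG stream per (seed, operation), so a
# partial re-run of any stage reproduces its output regardless of the others.
_OP_CODES = {
    "ancestral": 1,
    "haplotypes": 2,
    "long_reads": 3,
    "short_reads": 4,
    "callset_noise_a": 5,
    "callset_noise_b": 6,
}


def rng_for(seed: int, op: str) -> np.random.Generator:
    """Independent deterministic RNG stream keyed by (seed, operation name)."""
    return np.random.default_rng([int(seed), _OP_CODES[op]])
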