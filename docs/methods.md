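# Methods

## Scope and model

haplokit re-creates, at desk scale, the computational arm of a targeted
haplotype-resolved assembly workflow for a highly polymorphic diploid locus:
a region of a few hundred kilobases to a few megabases carrying roughly one
heterozygous SNV per kilobase, sparse small indels, and occasional
kilobase-scale structural variants, sequenced with long low-error reads
(HiFi-like) plus paired short reads for depth work. All inputs are produced
by the bundled simulator, so every downstream contract is checked against
exactly known truth rather than against external tools.

## Simulator

The ancestral sequence is i.i.d. with a configurable GC fraction (default
0.41, a typical human value). Two haplotypes are derived by placing
heterozygous SNVs and small indels at per-bp rates and assigning each to a
haplotype uniformly; small indel lengths are geometric(p = 0.5) clipped to
1–10 bp so they stay below the structural-variant threshold. Structural
variants are only ever explicit — callers plant them — which keeps the truth
set exact. Applying the truth list to the ancestral sequence reproduces both
haplotypes bit for bit (a tested round-trip).

Long reads have normal(10 kb, 1 kb) lengths truncated to [1 kb, 4× mean]
(matching a size-selected 8–12 kb library), uniform starts, substitution
errors only, and are emitted on the forward strand — a simplification that
keeps assembly and tagging transparent; the alignment machinery itself is
strand-aware. Short-read pairs are FR-oriented, 150 bp, with fragment
lengths normal(400, 40), drawn per haplotype in proportion to its copy
number, which is the signal the aneuploidy stage recovers.

Default heterozygosity (1 SNV/kb) is a free parameter of the synthetic
design, not an inferred biological value. Two "platform" callsets are
emulated by independently degrading the truth callset (2 % false-negative
rate, 2×10⁻⁵ false SNVs per bp by default); they share no error process, so
the consensus intersection removes almost all false positives — a property
the suite tests directly.

What the simulator does **not** model: platform error profiles (homopolymer
bias, chimeras), linked-read barcodes, GC coverage bias, repeats beyond what
an i.i.d. sequence contains, and strandedness of long reads. Passing tests
therefore demonstrate the correctness of the pipeline's logic and math under
clean conditions, not robustness to real-data pathologies — repeat-dense
loci in particular would stress the unique-anchor assumptions harder than
any synthetic instance here does.

## Read placement

A single seeded locator serves recruitment, rescue, and interval assignment:
exact 21-mers sampled every 200 bp along the read are looked up in a
target index, chained colinearly by an O(n²) DP that tolerates offset shifts
up to 50 kb (so a read spanning a kilobase-scale deletion still places as
one chained alignment, the way a production mapper would), and scored by
edlib edit distance within constant-offset segments. A read is recruited
when the anchored span covers ≥ 80 % of it at ≥ 90 % identity. Reads
dominated by reference-absent insertion sequence fail the span floor and
are deliberately left for the rescue stage.

## Haplotagging and downsampling

At each consensus site covered by a read, the two allele contexts (allele
± 20 reference bases) are compared by edit distance against the read
subsequence near the site; the closer context wins the vote, ties are
uninformative. Majority assigns the read; vote ties or zero informative
sites leave it untagged (conservative, like standard phasing practice).

Downsampling treats the reference as fixed non-overlapping 10 kb tiles.
Within a window, overlapping reads are ranked by aligned length (ties by
id) and marked kept until overlap bases reach 30× the window size; a read
kept by any window is kept globally. Union semantics preserve contiguity
for assembly across window boundaries; the selection is idempotent, and the
suite checks it against a brute-force reimplementation. Each haplotype
partition and the untagged set are downsampled independently.

## Assembly

The assembler is a minimal greedy overlap-layout stand-in, adequate for
low-error well-covered targeted data and replaceable through the
`assembler` hook of `assemble_haplotype`: reads sorted longest-first seed
contigs; candidate overlaps are found through sampled 21-mer hits against
the contig ends, verified by banded edit distance at ≤ 1 % mismatch, and the
largest verified overhang extends the contig (minimum overlap 2 kb);
contained reads are absorbed as members. All tie-breaks are lexicographic,
so assembly is deterministic. With error-free tiling reads the output
equals the source haplotype exactly (tested).

Round 1 assembles partition ∪ untagged reads after downsampling and drops
contigs < 50 kb. Rescue realigns reads absent from the original recruitment
against the preliminary contigs (floor: ≥ 95 % identity over ≥ 80 % of the
read) and round 2 re-assembles round-1 reads plus rescues; when nothing is
rescued, round 1 stands. Round 2 is not re-downsampled, and the 50 kb filter
is applied to its output as well, falling back to the unfiltered contigs in
the degenerate case where nothing survives (only relevant for toy regions
shorter than the filter). Final assemblies are scaffolded for the
personal-reference step by simple concatenation of contigs in reference
order — no gap estimation.

## Evaluation metrics

- optimal k: k = log₄(L(1−e)/e), reported to two decimals together with
  round(k) as the practical counting k (16.04 → 16 for a 4,548,949 bp
  region at e = 0.001). Strictly increasing in L, decreasing in e.
- Completeness: distinct canonical read k-mers with multiplicity ≥ 2 are
  "reliable" (singletons are dominated by sequencing errors); completeness
  is the fraction present in the assembly. A haplotype-specific k-mer set
  can be supplied to restrict the denominator; the default uses all
  reliable k-mers.
- Consensus QV: assembly k-mer positions whose k-mer has no read support
  imply per-base error E = 1 − (1 − b/T)^(1/k), QV = −10·log₁₀E, capped at
  99 when b = 0.
- NGA50/LGA50, coverage, duplication: computed over per-contig chain
  blocks; duplication is total aligned query bases over union-covered
  reference bases. K-mer counting is vectorized (2-bit packed canonical
  k-mers, k ≤ 31), with a pure-Python Counter used as the oracle in tests.

## Variant calling

Anchors are 31-mers unique in both the haplotype and the reference
(uniqueness in both avoids repeat-induced false chains at 1 SNV/kb
divergence); the longest strictly-increasing chain (patience LIS) is
segmented into exact-match blocks. Gap decomposition: both sides < 50 bp,
or net difference < 50 bp → end-to-end edlib alignment into per-base SNVs
and anchored indels; net difference ≥ 50 bp → one structural
deletion/insertion of the net size; both sides ≥ 50 bp with a large net
difference → a DEL+INS pair (a breakend-free representation of a complex
replacement). Every call is normalized (left-aligned, trimmed) before
output, and classified by net size, so a 49 bp event is an indel and a
50 bp event an SV — the boundary is tested. Chains spanning < 10 kb emit
nothing, mirroring the minimum-region constraint of assembly-based callers.
With an exact assembly the calls equal the normalized simulator truth
(tested as a set equality).

## Aneuploidy profile

Personal references embed each haplotype in the reference context; at desk
scale the "rest of the genome" is a pair of simulated flanking decoys
rather than a full genome. Mates are placed by exact matching (both
strands); a read is kept for haplotype i only if it matches i exactly and
the other haplotype not at all — the zero-edit unique filter. Per-base
depth is lifted to reference coordinates through the anchor chain: block
interiors map 1:1, substitution gaps map min(ref_gap, qry_gap) bases from
the left, deleted reference positions stay undefined, inserted haplotype
positions are dropped.

At each position carrying a variant between the haplotypes (and defined
depth on both), r = (d₁ + ε)/(d₂ + ε) with ε = 0.5 guarding division by
zero. The default smoothing takes log2 first and averages within fixed
10 kb windows: under Poisson depth the concavity of the log and the +ε
offset cancel almost exactly, making the estimator near-unbiased, whereas
averaging ratios first carries a +1/μ Jensen bias (about +5 % at 20×); the
alternative order remains available (`log_first=False`). Windows without
variant positions are filled from the nearest computed window, ties
resolved leftward, so fill never leaves the computed range. The overall
ratio is 2^median over the per-window values (median for robustness to
focal events; the mean is available via `use_mean`). The windows are
non-overlapping tiles; a step option for overlapped smoothing was
considered and left out as it changes none of the tested contracts.

The alignment-gain number (percent more region-aligned reads on the
personal reference than on the generic one) is reported as plumbing; its
magnitude on synthetic data depends directly on the simulated
heterozygosity and has no target value.

## Problem sizes and numerics

The shipped tests and the acceptance script use 60–500 kb regions, 30×
long reads, and 20× per-copy short reads — sizes chosen so the full suite
completes in a couple of minutes while keeping every statistical check
(Poisson/binomial bands, 5 % ratio tolerances) well-powered. Copy-ratio
recovery is validated at copy numbers 1:1, 2:1 and 3:1 within 5 %;
structural-variant recovery is validated exactly (1469 bp deletion, 968 bp
insertion). All randomness flows through per-operation numpy Generator
streams keyed on (seed, operation), so partial re-runs are reproducible and
the full pipeline is byte-deterministic for a fixed seed (tested).

## Known limitations

- The greedy assembler has no consensus polishing: with non-zero long-read
  error rates, residual read errors survive into contigs (QV quantifies
  this); error-free simulations assemble exactly.
- No inversion or translocation calling; complex gaps become DEL+INS pairs.
- Haplotagging assumes the consensus phase orientation is globally
  consistent (one phase set); switch errors are out of scope.
- Exact-match short-read placement means reads with any sequencing error
  are dropped by the zero-edit filter rather than realigned; this mirrors
  the strict NM:i:0 filter but discards more data as error rates rise.
- Multi-mapping within one haplotype is not resolved (first exact site
  wins); irrelevant for i.i.d. sequence, relevant for real repeats.
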