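# Methods

This note documents the models and numerical choices behind `exopair`: what
each stage computes, which knobs matter, what the synthetic generator does
and does not emulate, and where the design was genuinely open.

## Signal model

The raw signal is a multiset of 5′-end tag coordinates per (chromosome,
strand). ChIP-exo's lambda exonuclease digests toward the crosslink from
both sides, so a protein crosslinked at position `x` with a protected
footprint of half-width `b` yields forward-strand (W) 5′ ends concentrated
near `x − b` and reverse-strand (C) 5′ ends near `x + b`. A W/C peak couple
("peak-pair") therefore brackets the crosslink: the pair midpoint estimates
`x` and half the span estimates `b`. All coordinates are 0-based, intervals
half-open; SAM input is converted from 1-based on ingest, and the 5′ end of
a reverse-strand read is its rightmost aligned base.

## Peak calling

Per strand, density is the un-normalized Gaussian-kernel sum
`d(p) = Σ_t exp(−(p−t)²/2σ²)` evaluated at integer bp. Defaults: σ = 20 bp,
kernel truncated at ±4σ (beyond which the contribution is exactly zero —
densities are computed by convolution over the padded tag span, which is
exact under truncation). The kernel is deliberately not a normalized KDE:
only the argmax structure and relative heights matter, and heights remain
comparable within a dataset.

Candidate summits are local maxima; retained summits are chosen greedily in
descending height under an exclusion zone of 40 bp (center-to-center: a
candidate < 40 bp from a retained summit is dropped). Consequences that the
tests assert: no two retained same-strand summits are ever < 40 bp apart,
and two equal tag clusters must be ≥ ~60 bp apart before the smoothed
density is even bimodal — clusters 30 bp apart merge into a single maximum
between them. The exclusion zone thus bounds the resolution of separating
adjacent complexes.

Numerical conventions: densities within a relative 1e-9 of each other are
treated as tied; a tied plateau yields one candidate at its leftmost
position, and greedy ordering quantizes heights to 1e-6 before breaking
ties leftmost. This makes the summit well-defined when the continuous
maximum falls halfway between integer positions, and keeps the caller
invariant to floating-point summation order (verified against a direct-sum
brute-force implementation). Per-peak `tag_count` is the number of raw tags
within ± half the exclusion zone (±20 bp) of the summit; a retained summit
with zero tags in that window (possible between two distant clusters) is
not emitted. Replicates are merged as a coordinate-wise multiset union
before final calls.

## Pairing and filters

A W peak at `w` may pair with a C peak at `c` iff `0 ≤ c − w ≤ 80` — the
C border must be 0–80 bp in the 3′ direction, because exo borders flank the
footprint with the W border on the left. Each peak joins at most one pair.
Conflicts resolve by (1) smallest span, (2) larger combined tag count,
(3) leftmost W summit; smallest-span-first favors tight footprints, and the
alternatives differ only on pathological overlaps (covered by the
exhaustive-assignment oracle tests). Pair occupancy = sum of the two peak
tag counts; midpoint = floor of the summit mean. Filters: midpoint inside a
blacklist interval (half-open) removes the pair; occupancy must be
strictly > 4 tags (≥ 5 retained). Cross-dataset matching declares a
location reproduced when the other dataset has a midpoint within ≤ w bp
(midpoint distance, not feature overlap — the natural reading for 1-bp
locations).

## TSS assignment and annotation

Eligibility is unsigned distance ≤ 500 bp from midpoint to TSS; the nearest
TSS wins, equidistant ties go to the smaller coordinate. For multi-TSS
genes the nearest TSS is primary. Signed offsets are oriented by gene
strand (negative = upstream), so mirroring the genome and flipping strands
leaves offsets invariant — a property test. A pair is assigned to at most
one gene; a gene may accumulate several pairs (that is what "complexes per
island" measures). CpG-island membership is midpoint-in-interval; the
island summary reports both locations-per-occupied-island and the fraction
of assigned genes whose promoter island holds ≥ 1 location, since "island
overlap" can be read either way. Segment classification takes the first
containing interval in file order.

## Composite profiles

Offsets are binned in non-overlapping 10-bp intervals (`floor(offset/10)`,
offset 0 in [0,10)), window ±500 bp for mRNA TSSs and ±200 bp for tRNA
genes (matching the assignment windows). Input normalization: both matrices
are converted to RPKM (`count / (bin_kb × total_tags/1e6)`, the depth
denominator being all tags on both strands — a documented choice, as is the
convention that zero-Input bins are missing rather than infinite), then
divided bin-wise. Composites average over genes (missing bins excluded) and
are scaled to sum to 100 *after* averaging. Row sorts (by inter-complex
distance, island length or occupancy) return a permutation that is applied
to all linked factor matrices, never destructively. The modal peak-pair
offset is the 1-bp histogram mode, ties to smallest |offset|.

## Occupancy statistics

Adjacent-complex records are (distance, left occupancy, right occupancy)
for consecutive locations within a group (island or promoter). The
sliding-window trace sorts records by distance and computes, over 30
consecutive records, the sample SD (n−1) of the within-pair occupancy
difference against the window's median distance. The within-pair difference
is the statistic that discriminates coordinately regulated neighbors
(difference ≈ 0, low SD) from independently regulated ones (SD ≈ √2 × the
between-site spread); the SD of the pooled occupancies would be blind to
that distinction. Stratified Pearson r between left and right occupancies
is reported with n, absent when n < 3. Expression comparisons use
log2(v+1) (pseudocount documented; the transform is applied before
median-centering over the genes entering the analysis), pairwise-complete
on nonzero values; the moving-average trend uses a 100-gene window, step 1,
after sorting by the x series.

## Multi-sample clustering

The occupancy matrix is genes (detected in ≥ 1 sample) × samples, values =
summed assigned-pair occupancy, 0 = not detected. Column normalization:
log2(v+1) over detected entries, centered on the column mean of those
entries; zeros stay flagged as "not detected". Group 1 = detected in every
sample. The remainder goes to k-means (k = 3 by default, k-means++ with 100
restarts, fixed seed); not-detected cells are imputed one log2 unit below
the column's observed minimum, keeping "absent" distinct from "low" without
dropping rows — the main open design risk here, since no convention is
canonical. Cluster labels are renumbered by descending mean occupancy and
rows sorted within groups by cross-sample mean. Samples are clustered with
average linkage on 1 − Pearson r over genes detected in both samples of a
pair (choice of distance and linkage is configurable; correlation distance
is robust to per-sample depth), serialized as Newick.

## Synthetic data

The generator is the study's test bed. Defaults and what they emulate:

| parameter | default | rationale |
|---|---|---|
| factor offsets | TFIIB −20, TBP −20, Pol II +50, TBP at tRNA −21 bp | canonical PIC geometry: TBP/TFIIB over the TATA region ~20 bp upstream, paused Pol II ~50 bp downstream, TBP (via TFIIIB) ~21 bp upstream of tRNA TSSs |
| divergent fraction / offset | 0.5, N(250, 40) bp upstream, opposite strand | divergent TSSs are common and sit roughly 250 bp upstream; partners are physically distinct complexes with their own crosslink points and independently drawn occupancies |
| border half-width | truncated normal 15 ± 3 bp, min 5, shared by both strands of a site | exo footprint half-width; sharing keeps pair spans symmetric |
| tag jitter | N(0, 1) bp, rounded | the source data's noise structure is unpublished; small symmetric jitter is our choice |
| occupancy | negative binomial, mean 30/strand, size 5 | overdispersion mirrors real ChIP enrichment spread and gives heatmaps a realistic dynamic range |
| background | Poisson, 1 tag/kb/strand, uniform | unstructured library noise |
| secondary signal fraction | 0.24 | divergent (antisense) RNA is scaled so it contributes 24% of total TSS-linked signal |
| CpG islands | half-width 300 bp, center 100 bp downstream of the TSS | islands engulf the core promoter with their center displaced downstream |
| genes | ≥ 2 kb apart, strands random | makes TSS assignment unambiguous by construction |

Per-site emission: half-width `b` drawn once, occupancy `n` drawn once,
then `n` W tags at `x − b` and `n` C tags at `x + b`, each with jitter.
Everything is deterministic under the config seed (verified bit-identical),
and tag counts are conserved (site tags + background = total).

Not emulated: PCR duplicates, mappability gaps, sequence composition,
fragment-length variation, copy-number structure, multi-TSS genes, and
correlated occupancy between neighboring complexes. Passing recovery tests
therefore demonstrates the pipeline's correctness on the border-tag model,
not robustness to every artifact of real libraries.

## Problem sizes

The bundled study and the reproduction script use miniature genomes — 2–4
chromosomes of 1–1.5 Mb with 400–1,000 genes — which are large enough for
every statistic to concentrate (SEMs of a few percent) while the full suite
runs in well under a minute per analysis. The published genome-wide totals
(tens of thousands of locations from ~10⁸-read libraries) are inputs to the
summary arithmetic, not quantities re-estimated here.

## Known limitations

* The exclusion-zone greedy rule reproduces the published resolution bound,
  but the original caller's exact tie-breaking is unpublished; ours
  (height, then leftmost) is documented and oracle-tested.
* Pair occupancy, RPKM depth denominators and k-means zero-imputation have
  no canonical published definitions; each choice is documented above and
  isolated behind one function.
* With the default σ = 20, composite tag traces around a planted site are
  border-shaped (bimodal at ±b around the crosslink), so the composite
  argmax bin can sit on either border; the peak-pair modal offset is the
  stable location estimator.
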