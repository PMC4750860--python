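# exopair

Strand-separated ChIP-exo peak-pair analysis of transcription pre-initiation
complexes (PICs) at base-pair resolution.

ChIP-exo trims immunoprecipitated chromatin with lambda exonuclease up to a
few bp of the protein–DNA crosslink, leaving strand-specific 5′ "borders":
forward-strand (W) read 5′ ends pile up just left of the protected footprint
and reverse-strand (C) 5′ ends just right of it. `exopair` turns those
borders back into bound locations and runs the promoter-architecture
analyses that exploit this resolution: where general factors (TBP, TFIIB)
sit relative to the TSS, where paused RNA polymerase II sits, whether
divergent antisense transcription comes from physically distinct complexes,
how complexes populate CpG islands, and how TFIIB occupancy varies across
cell lines.

## The method

1. **Peak calling** (per chromosome, per strand): tag 5′ ends are smoothed
   with an un-normalized Gaussian kernel,
   `d(p) = Σ_t exp(−(p−t)²/2σ²)` with σ = 20 bp, kernel truncated at ±4σ.
   Local maxima of `d` are retained greedily by height subject to an
   exclusion zone: no two retained summits on a strand may be < 40 bp apart.
   The exclusion zone bounds resolution — two bound locations closer than
   ~40 bp cannot be separated.
2. **Peak pairing**: a W peak at `w` pairs with a C peak at `c` iff
   `0 ≤ c − w ≤ 80` (the C border must lie 0–80 bp 3′ of the W border).
   Each peak joins at most one pair; conflicts resolve smallest span first.
   The pair midpoint `⌊(w+c)/2⌋` estimates the crosslink point; occupancy is
   the summed raw tag count of the two peaks. Pairs with midpoint in a
   blacklist interval or with ≤ 4 tags are discarded.
3. **Annotation**: each location is assigned to the nearest TSS within
   500 bp (nearest TSS of a multi-TSS gene = primary TSS); signed offsets
   are strand-oriented (negative = upstream). Locations are intersected with
   CpG islands and genome-segment classes.
4. **Profiles and statistics**: tags or pair midpoints are binned in 10-bp
   intervals around the TSS, normalized bin-wise as ChIP RPKM / Input RPKM,
   and averaged as percent of total; inter-complex spacings, occupancy
   correlations, moving-average expression trends and cross-sample
   occupancy clustering (detection Group 1 + k-means Groups 2–4, sample
   dendrogram on 1 − Pearson r) complete the analysis.

A synthetic-data module plants all of this structure (factor offsets
TFIIB/TBP −20, Pol II +50, TBP −21 at tRNA genes; divergent partners ~250 bp
upstream on the opposite strand; negative-binomial occupancy; Poisson
background) with recoverable ground truth, so the whole pipeline is testable
without external data.

## Worked example

```sh
exopair simulate --seed 2 --out demo/
exopair callpeaks --sigma 20 --exclusion 40 --in demo/tags_TFIIB.bed --out demo/peaks.tsv
exopair pair --peaks demo/peaks.tsv --blacklist demo/blacklist.bed --max-span 80 --min-tags 4 --out demo/pairs.tsv
```

prints

```
wrote synthetic genome with 470 planted sites to demo
3975 peaks -> demo/peaks.tsv
149 peak-pairs -> demo/pairs.tsv
```

i.e. the simulated genome planted 470 factor sites (100 mRNA genes × 3
factors, divergent partners at roughly half of them, 20 tRNA genes);
strand-separated calling found 3,975 candidate peaks (most are single
background tags), and pairing plus the blacklist and >4-tag filters reduced
them to 149 confident TFIIB bound locations — essentially one per planted
TFIIB complex that passed the occupancy threshold. `exopair run --seed 3 --out rundir/` executes every stage and
writes a JSON manifest.

The numbered scripts under `analysis/` run the same stages as a narrative
study on a larger simulated genome (800 genes, 4 pseudo-cell-lines) and
write tables under `results/analysis/`: peak-pair recovery rates (≥99.9% of
planted crosslinks within 5 bp), modal offsets (TFIIB −20, Pol II +50, TBP
−21 at tRNA genes), CpG-island occupancy, occupancy-vs-RNA correlations and
the cross-sample groups and dendrogram.

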