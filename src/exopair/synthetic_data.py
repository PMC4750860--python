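"""Synthetic ChIP-exo genome and tag generator with recoverable ground truth.

The generator plants a miniature genome annotation (well-separated mRNA TSSs,
tRNA TSSs, CpG islands, a blacklist, genome-segment classes) and emits
exonuclease-border tag datasets with the structure the downstream analysis
assumes:

* each planted protein-DNA crosslink point at genomic position ``x`` with exo
  footprint half-width ``b`` produces forward-strand (W) 5' ends concentrated
  at ``x - b`` and reverse-strand (C) 5' ends at ``x + b``, with small
  symmetric jitter — the strand-separated border pattern left by lambda
  exonuclease on either side of the crosslink;
* general factors sit at fixed strand-oriented offsets from the TSS (TFIIB
  and TBP at -20, paused Pol II at +50, TBP at tRNA genes at -21);
* a configurable fraction of genes carries a divergent partner complex on
  the opposite strand, centered a few hundred bp upstream — a physically
  distinct initiation complex, not a mirrored copy of the primary one;
* per-site occupancy is negative binomial (overdispersed, like real ChIP
  enrichment); uniform Poisson background tags are added per strand;
* multiple pseudo-cell-line samples share a core set of occupied genes and
  differ in a sample-specific subset.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .genome_io import C, IntervalSet, TagDataset, TssRecord, W

FACTORS = ("TFIIB", "TBP", "PolII")


@dataclass(frozen=True)
class SimConfig:
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 100
    n_trna: int = 20
    divergent_fraction: float = 0.5
    divergent_offset_mean: float = 250.0
    divergent_offset_sd: float = 40.0
    factor_offsets: Mapping[str, int] = field(default_factory=lambda: {
        "TFIIB": -20, "TBP": -20, "PolII": 50, "TBP_tRNA": -21})
    border_halfwidth_mean: float = 15.0
    border_halfwidth_sd: float = 3.0
    border_halfwidth_min: int = 5
    tags_per_site_mean: float = 30.0
    nb_dispersion: float = 5.0          # NB size parameter; larger = less overdispersed
    jitter_sd: float = 1.0
    background_rate: float = 1.0        # tags per kb per strand
    cpg_island_halfwidth: int = 300
    cpg_center_offset: int = 100        # island center ~100 bp downstream of TSS
    n_samples: int = 4
    sample_specific_fraction: float = 0.3
    rna_noise_sd: float = 0.5           # log2 units
    secondary_signal_fraction: float = 0.24
    min_gene_spacing: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for name in ("chrom_length", "n_chroms", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("divergent_fraction", "sample_specific_fraction",
                     "secondary_signal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        per_chrom = -(-self.n_genes // self.n_chroms) + -(-self.n_trna // self.n_chroms)
        usable = self.chrom_length - 2 * self.min_gene_spacing
        if per_chrom * self.min_gene_spacing > usable:
            raise ValueError("config implies overlapping genes: "
                             f"{per_chrom} TSSs cannot be spaced {self.min_gene_spacing} bp "
                             f"apart on a {self.chrom_length} bp chromosome")


@dataclass(frozen=True)
class Site:
    factor: str
    chrom: str
    midpoint: int       # true crosslink point
    strand: str         # strand of the associated TSS
    occupancy: int      # planted tags per strand at this site
    gene_id: str
    site_class: str     # primary | divergent | tRNA


@dataclass
class GroundTruth:
    sites: list[Site]
    gene_occupancy: dict[str, float]   # per-gene planted (primary TFIIB) occupancy
    tss: dict[str, TssRecord]
    trna: dict[str, TssRecord]

    def by_factor(self, factor: str) -> list[Site]:
        return [s for s in self.sites if s.factor == factor]


@dataclass
class Annotations:
    tss_set: dict[str, TssRecord]
    trna_set: dict[str, TssRecord]
    cpg_islands: IntervalSet
    blacklist: IntervalSet
    segments: IntervalSet


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


def _place_tss(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, int, str]]:
    """Evenly strided TSS slots with random sub-stride placement; spacing
    >= min_gene_spacing by construction so assignments are unambiguous."""
    total = config.n_genes + config.n_trna
    out: list[tuple[str, int, str]] = []
    per_chrom = -(-total // config.n_chroms)
    margin = config.min_gene_spacing
    for c in range(config.n_chroms):
        n_here = min(per_chrom, total - len(out))
        if n_here <= 0:
            break
        stride = (config.chrom_length - 2 * margin) / n_here
        if stride < config.min_gene_spacing:
            raise ValueError("config implies overlapping genes")
        for i in range(n_here):
            slack = max(0, int(stride) - config.min_gene_spacing)
            pos = int(margin + i * stride) + int(rng.integers(0, slack + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            out.append((f"chr{c + 1}", pos, strand))
    return out


def generate_annotations(config: SimConfig) -> Annotations:
    config.validate()
    rng = _rng(config, 1)
    slots = _place_tss(config, rng)
    rng.shuffle(slots)
    gene_slots = slots[: config.n_genes]
    trna_slots = slots[config.n_genes: config.n_genes + config.n_trna]

    tss_set = {f"gene{i:05d}": TssRecord(f"gene{i:05d}", chrom, strand, [pos])
               for i, (chrom, pos, strand) in enumerate(sorted(gene_slots))}
    trna_set = {f"trna{i:04d}": TssRecord(f"trna{i:04d}", chrom, strand, [pos])
                for i, (chrom, pos, strand) in enumerate(sorted(trna_slots))}

    islands = IntervalSet()
    for rec in tss_set.values():
        tss = rec.positions[0]
        sign = 1 if rec.strand == "+" else -1
        center = tss + sign * config.cpg_center_offset
        islands.add(rec.chrom, center - config.cpg_island_halfwidth,
                    center + config.cpg_island_halfwidth, rec.gene_id)

    # blacklist: intergenic decoys plus one interval deliberately covering a
    # planted primary site, so the midpoint filter has something real to remove
    blacklist = IntervalSet()
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        start = int(0.95 * config.chrom_length)
        blacklist.add(chrom, start, start + 500, "decoy")
    first = next(iter(tss_set.values()))
    sign = 1 if first.strand == "+" else -1
    site = first.positions[0] + sign * config.factor_offsets["TFIIB"]
    blacklist.add(first.chrom, site - 25, site + 25, "over_site")

    segments = IntervalSet()
    classes = ("enhancer", "transcription", "heterochromatin")
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        promoters = sorted(rec.positions[0] for rec in tss_set.values()
                           if rec.chrom == chrom)
        edges = [0]
        for tss in promoters:
            lo, hi = max(0, tss - 500), min(config.chrom_length, tss + 500)
            if lo > edges[-1]:
                edges.append(lo)
            edges.append(hi)
        if edges[-1] < config.chrom_length:
            edges.append(config.chrom_length)
        k = 0
        for lo, hi in zip(edges, edges[1:]):
            if lo >= hi:
                continue
            is_promoter = any(tss - 500 <= lo < tss + 500 for tss in promoters)
            label = "promoter" if is_promoter else classes[k % len(classes)]
            if not is_promoter:
                k += 1
            segments.add(chrom, lo, hi, label)
    return Annotations(tss_set, trna_set, islands, blacklist, segments)


def _draw_occupancy(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    # NB parameterized by size r and mean m: p = r/(r+m)
    r = config.nb_dispersion
    p = r / (r + config.tags_per_site_mean)
    return np.maximum(rng.negative_binomial(r, p, size=n), 1)


def plant_sites(annotations: Annotations, config: SimConfig) -> GroundTruth:
    """Plant crosslink points for each factor at every mRNA gene (plus
    divergent partners) and TBP at every tRNA gene."""
    rng = _rng(config, 2)
    sites: list[Site] = []
    gene_occ: dict[str, float] = {}
    genes = sorted(annotations.tss_set)
    occ = _draw_occupancy(rng, config, len(genes))
    divergent = rng.random(len(genes)) < config.divergent_fraction
    div_dist = np.maximum(
        np.round(rng.normal(config.divergent_offset_mean,
                            config.divergent_offset_sd, len(genes))), 120).astype(int)
    div_occ = _draw_occupancy(rng, config, len(genes))
    for i, gene in enumerate(genes):
        rec = annotations.tss_set[gene]
        tss = rec.positions[0]
        sign = 1 if rec.strand == "+" else -1
        gene_occ[gene] = float(occ[i])
        for factor in FACTORS:
            x = tss + sign * config.factor_offsets[factor]
            sites.append(Site(factor, rec.chrom, x, rec.strand, int(occ[i]),
                              gene, "primary"))
        if divergent[i]:
            d_tss = tss - sign * div_dist[i]
            d_strand = "-" if rec.strand == "+" else "+"
            d_sign = -sign
            for factor in FACTORS:
                x = d_tss + d_sign * config.factor_offsets[factor]
                sites.append(Site(factor, rec.chrom, x, d_strand, int(div_occ[i]),
                                  gene, "divergent"))
    trnas = sorted(annotations.trna_set)
    t_occ = _draw_occupancy(rng, config, len(trnas))
    for i, trna in enumerate(trnas):
        rec = annotations.trna_set[trna]
        tss = rec.positions[0]
        sign = 1 if rec.strand == "+" else -1
        x = tss + sign * config.factor_offsets["TBP_tRNA"]
        sites.append(Site("TBP_tRNA", rec.chrom, x, rec.strand, int(t_occ[i]),
                          trna, "tRNA"))
    return GroundTruth(sites, gene_occ, annotations.tss_set, annotations.trna_set)


def simulate_exo_tags(truth: GroundTruth, config: SimConfig,
                      factor: str | None = None, salt: int = 3,
                      sample: str = "chip") -> TagDataset:
    """Emit border tags for every planted site (optionally one factor) plus
    uniform Poisson background on each strand of each chromosome."""
    sites = truth.sites if factor is None else [s for s in truth.sites
                                                if s.factor == factor]
    if not sites:
        raise ValueError("no planted sites to simulate")
    rng = _rng(config, salt)
    ds = TagDataset(sample=sample)
    per_key: dict[tuple[str, str], list[np.ndarray]] = {}
    for site in sorted(sites, key=lambda s: (s.chrom, s.midpoint, s.factor)):
        b = max(config.border_halfwidth_min,
                int(round(rng.normal(config.border_halfwidth_mean,
                                     config.border_halfwidth_sd))))
        n = site.occupancy
        for strand, border in ((W, site.midpoint - b), (C, site.midpoint + b)):
            jit = (np.round(rng.normal(0.0, config.jitter_sd, n)).astype(np.int64)
                   if config.jitter_sd > 0 else np.zeros(n, dtype=np.int64))
            coords = np.maximum(border + jit, 0)
            per_key.setdefault((site.chrom, strand), []).append(coords)
    lam = config.background_rate * config.chrom_length / 1000.0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for strand in (W, C):
            n_bg = rng.poisson(lam)
            coords = rng.integers(0, config.chrom_length, n_bg)
            per_key.setdefault((chrom, strand), []).append(coords.astype(np.int64))
    for (chrom, strand), chunks in per_key.items():
        ds.add_tags(chrom, strand, np.concatenate(chunks))
    return ds


def simulate_input_tags(config: SimConfig, rate: float | None = None,
                        salt: int = 4) -> TagDataset:
    """Uniform background-only dataset (the Input/control)."""
    rng = _rng(config, salt)
    rate = config.background_rate if rate is None else rate
    ds = TagDataset(sample="input")
    lam = rate * config.chrom_length / 1000.0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for strand in (W, C):
            n = rng.poisson(lam)
            if n:
                ds.add_tags(chrom, strand, rng.integers(0, config.chrom_length, n))
    return ds


def simulate_rna_levels(truth: GroundTruth, config: SimConfig,
                        salt: int = 5) -> dict[str, float]:
    """Per-gene RNA level: planted occupancy with log-normal noise; the RNA of
    divergent (antisense) sites is scaled down by secondary_signal_fraction,
    mirroring the instability of divergent transcripts."""
    rng = _rng(config, salt)
    out: dict[str, float] = {}
    div_occ = {s.gene_id: s.occupancy for s in truth.sites
               if s.site_class == "divergent" and s.factor == "TFIIB"}
    for gene in sorted(truth.gene_occupancy):
        base = truth.gene_occupancy[gene]
        noise = rng.normal(0.0, config.rna_noise_sd) if config.rna_noise_sd > 0 else 0.0
        out[gene] = float(2.0 ** (np.log2(base) + noise))
        if gene in div_occ:
            d_noise = rng.normal(0.0, config.rna_noise_sd) if config.rna_noise_sd > 0 else 0.0
            # secondary_signal_fraction is a share of TOTAL signal, so the
            # antisense/sense scale factor is f / (1 - f)
            f = config.secondary_signal_fraction
            scale = f / (1.0 - f) if f < 1.0 else 1.0
            out[gene + ":antisense"] = float(
                scale * 2.0 ** (np.log2(div_occ[gene]) + d_noise))
    return out


def simulate_samples(config: SimConfig) -> tuple[Annotations, dict[str, GroundTruth]]:
    """Pseudo-cell-line panel: a shared core of occupied genes plus a
    sample-specific subset per sample; occupancies redrawn per sample."""
    annotations = generate_annotations(config)
    rng = _rng(config, 6)
    genes = sorted(annotations.tss_set)
    n = len(genes)
    n_specific = int(round(config.sample_specific_fraction * n))
    specific = set(rng.choice(n, size=n_specific, replace=False).tolist())
    owner = {g: int(rng.integers(0, config.n_samples)) for g in specific}
    truths: dict[str, GroundTruth] = {}
    base = plant_sites(annotations, config)
    for s in range(config.n_samples):
        occ = _draw_occupancy(_rng(config, 100 + s), config, n)
        keep_idx = {i for i in range(n) if i not in specific or owner[i] == s}
        sites = []
        gene_occ = {}
        for site in base.sites:
            if site.site_class == "tRNA":
                sites.append(site)
                continue
            gi = genes.index(site.gene_id)
            if gi not in keep_idx:
                continue
            sites.append(replace(site, occupancy=int(occ[gi])))
            if site.factor == "TFIIB" and site.site_class == "primary":
                gene_occ[site.gene_id] = float(occ[gi])
        truths[f"cell{s + 1}"] = GroundTruth(sites, gene_occ,
                                             annotations.tss_set,
                                             annotations.trna_set)
    return annotations, truths
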