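"""Generator determinism, planted-structure statistics, border-tag geometry."""

import dataclasses

import numpy as np
import pytest

from exopair.genome_io import C, W
from exopair.synthetic_data import (SimConfig, generate_annotations, plant_sites,
                                    simulate_exo_tags, simulate_input_tags,
                                    simulate_rna_levels, simulate_samples)


def _cfg(**kw):
    base = dict(n_chroms=1, chrom_length=300_000, n_genes=30, n_trna=5, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_overlapping_genes_rejected(self):
        with pytest.raises(ValueError, match="overlapping genes"):
            SimConfig(n_chroms=1, chrom_length=10_000, n_genes=100).validate()

    def test_probabilities_validated(self):
        with pytest.raises(ValueError, match="probability"):
            SimConfig(divergent_fraction=1.5).validate()


class TestAnnotations:
    def test_fixed_seed_is_deterministic(self):
        cfg = _cfg(n_genes=10)
        a = generate_annotations(cfg)
        b = generate_annotations(cfg)
        assert {g: r.positions for g, r in a.tss_set.items()} == \
               {g: r.positions for g, r in b.tss_set.items()}
        assert list(a.cpg_islands) == list(b.cpg_islands)
        assert len(a.tss_set) == 10 and len(a.cpg_islands) == 10

    def test_tss_spacing_at_least_min_gene_spacing(self):
        cfg = _cfg(n_genes=50, n_trna=20, chrom_length=500_000)
        ann = generate_annotations(cfg)
        pos = sorted(r.positions[0] for r in
                     list(ann.tss_set.values()) + list(ann.trna_set.values()))
        assert min(b - a for a, b in zip(pos, pos[1:])) >= cfg.min_gene_spacing

    def test_cpg_island_centered_downstream_of_tss(self):
        ann = generate_annotations(_cfg())
        islands = {lab: (s + e) // 2 for _, s, e, lab in ann.cpg_islands}
        for gene, rec in ann.tss_set.items():
            sign = 1 if rec.strand == "+" else -1
            assert islands[gene] == rec.positions[0] + sign * 100

    def test_blacklist_overlaps_one_planted_site(self):
        ann = generate_annotations(_cfg())
        truth = plant_sites(ann, _cfg())
        covered = [s for s in truth.sites
                   if ann.blacklist.contains_point(s.chrom, s.midpoint)]
        assert covered

    def test_segments_partition_each_chromosome(self):
        cfg = _cfg()
        ann = generate_annotations(cfg)
        ivs = sorted((s, e) for chrom, s, e, _ in ann.segments if chrom == "chr1")
        assert ivs[0][0] == 0 and ivs[-1][1] == cfg.chrom_length
        assert all(a[1] == b[0] for a, b in zip(ivs, ivs[1:]))

    def test_divergent_fraction_one_gives_partner_for_every_gene(self):
        cfg = _cfg(divergent_fraction=1.0)
        truth = plant_sites(generate_annotations(cfg), cfg)
        primary = {s.gene_id for s in truth.sites if s.site_class == "primary"}
        divergent = {s.gene_id for s in truth.sites if s.site_class == "divergent"}
        assert primary == divergent
        for s in truth.sites:
            if s.site_class == "divergent":
                rec = truth.tss[s.gene_id]
                # opposite strand, upstream of the mRNA TSS
                assert s.strand != rec.strand
                if rec.strand == "+":
                    assert s.midpoint < rec.positions[0]
                else:
                    assert s.midpoint > rec.positions[0]

    def test_divergent_spacing_matches_planted_distribution(self):
        """Mean primary-to-divergent TSS distance over ~1,000 genes recovers
        the configured 250 bp within 2 SEM."""
        cfg = SimConfig(n_chroms=4, chrom_length=1_500_000, n_genes=1000,
                        n_trna=0, divergent_fraction=1.0,
                        divergent_offset_mean=250.0, divergent_offset_sd=40.0,
                        seed=5)
        truth = plant_sites(generate_annotations(cfg), cfg)
        prim = {s.gene_id: s for s in truth.sites
                if s.site_class == "primary" and s.factor == "TFIIB"}
        dists = []
        for s in truth.sites:
            if s.site_class == "divergent" and s.factor == "TFIIB":
                rec = truth.tss[s.gene_id]
                sign = 1 if rec.strand == "+" else -1
                d_tss = s.midpoint - sign * 20  # undo the factor offset
                dists.append(abs(rec.positions[0] - d_tss))
        sem = 40.0 / np.sqrt(len(dists))
        assert len(dists) == 1000
        assert abs(np.mean(dists) - 250.0) < 2 * sem


class TestExoTags:
    def test_noise_free_borders_bracket_the_crosslink(self):
        """A site at the crosslink point x with half-width b and no jitter puts
        every W tag at x-b and every C tag at x+b."""
        cfg = _cfg(n_genes=1, n_trna=0, divergent_fraction=0.0, jitter_sd=0.0,
                   background_rate=0.0, border_halfwidth_sd=0.0,
                   border_halfwidth_mean=15.0)
        ann = generate_annotations(cfg)
        truth = plant_sites(ann, cfg)
        site, = [s for s in truth.sites if s.factor == "TFIIB"]
        tags = simulate_exo_tags(truth, cfg, factor="TFIIB")
        assert set(tags.tags(site.chrom, W).tolist()) == {site.midpoint - 15}
        assert set(tags.tags(site.chrom, C).tolist()) == {site.midpoint + 15}
        assert tags.tags(site.chrom, W).size == site.occupancy

    def test_tag_count_conservation(self):
        cfg = _cfg(jitter_sd=0.0, background_rate=0.0)
        truth = plant_sites(generate_annotations(cfg), cfg)
        tags = simulate_exo_tags(truth, cfg, factor="TFIIB")
        planted = sum(s.occupancy for s in truth.sites if s.factor == "TFIIB")
        assert tags.total == 2 * planted  # one border per strand

    def test_background_poisson_mean(self):
        cfg = SimConfig(n_chroms=1, chrom_length=1_000_000, n_genes=1,
                        n_trna=0, background_rate=1.0, seed=3)
        ds = simulate_input_tags(cfg)
        for strand in (W, C):
            n = ds.tags("chr1", strand).size
            assert abs(n - 1000) < 3 * np.sqrt(1000)

    def test_zero_rate_input_is_empty(self):
        assert simulate_input_tags(_cfg(), rate=0.0).total == 0

    def test_fixed_seed_reproducibility(self):
        cfg = _cfg()
        truth = plant_sites(generate_annotations(cfg), cfg)
        assert simulate_exo_tags(truth, cfg) == simulate_exo_tags(truth, cfg)
        assert simulate_input_tags(cfg) == simulate_input_tags(cfg)


class TestRnaLevels:
    def test_zero_noise_gives_perfect_log_correlation(self):
        cfg = _cfg(rna_noise_sd=0.0)
        truth = plant_sites(generate_annotations(cfg), cfg)
        rna = simulate_rna_levels(truth, cfg)
        genes = sorted(truth.gene_occupancy)
        r = np.corrcoef(np.log2([rna[g] for g in genes]),
                        np.log2([truth.gene_occupancy[g] for g in genes]))[0, 1]
        assert r == pytest.approx(1.0)

    def test_correlation_decreases_monotonically_with_noise(self):
        cfg0 = SimConfig(n_chroms=2, chrom_length=1_000_000, n_genes=600,
                         n_trna=0, seed=7)
        truth = plant_sites(generate_annotations(cfg0), cfg0)
        genes = sorted(truth.gene_occupancy)
        occ = np.log2([truth.gene_occupancy[g] for g in genes])
        rs = []
        for sd in (0.0, 0.5, 2.0, 8.0):
            cfg = dataclasses.replace(cfg0, rna_noise_sd=sd)
            rna = simulate_rna_levels(truth, cfg)
            rs.append(np.corrcoef(np.log2([rna[g] for g in genes]), occ)[0, 1])
        assert rs[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(rs, rs[1:]))
        assert rs[-1] < 0.3

    def test_divergent_rna_share_matches_secondary_signal_fraction(self):
        """With equal planted occupancies, summed antisense RNA over summed
        sense RNA recovers the configured 24% secondary-signal share."""
        cfg = SimConfig(n_chroms=4, chrom_length=1_500_000, n_genes=1000,
                        n_trna=0, divergent_fraction=1.0, rna_noise_sd=0.0,
                        secondary_signal_fraction=0.24, seed=9)
        truth = plant_sites(generate_annotations(cfg), cfg)
        rna = simulate_rna_levels(truth, cfg)
        sense = sum(v for g, v in rna.items() if not g.endswith(":antisense"))
        anti = sum(v for g, v in rna.items() if g.endswith(":antisense"))
        # sense and divergent occupancies are drawn from the same NB model,
        # so the share of total concentrates near the configured fraction
        assert anti / (anti + sense) == pytest.approx(0.24, rel=0.10)


class TestMultiSamplePanel:
    def test_shared_and_specific_detection_structure(self):
        cfg = _cfg(n_genes=60, n_samples=3, sample_specific_fraction=0.4)
        _, truths = simulate_samples(cfg)
        assert sorted(truths) == ["cell1", "cell2", "cell3"]
        detected = {s: set(t.gene_occupancy) for s, t in truths.items()}
        shared = set.intersection(*detected.values())
        union = set.union(*detected.values())
        assert len(union) == 60
        assert len(shared) == pytest.approx(36, abs=1)  # 60 * (1 - 0.4)
        specific = union - shared
        for g in specific:
            assert sum(g in d for d in detected.values()) == 1
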