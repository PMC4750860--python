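"""End-to-end orchestration: simulate -> call peaks -> pair -> annotate ->
profile -> stats -> multisample, with a JSON run manifest.

Reruns with an identical config reproduce identical outputs byte-for-byte
(the manifest's parameter block excludes timestamps)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np

from . import composite_profiles as cp
from . import genome_io as gio
from . import multi_sample as ms
from . import occupancy_stats as ostats
from . import peak_calling as pc
from . import peak_pairing as pp
from . import synthetic_data as sd
from . import tss_annotation as ta


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "sim": {},              # overrides for SimConfig fields
    "sigma": 20.0,
    "exclusion_zone": 40,
    "max_span": 80,
    "min_tags": 4,
    "tss_max_dist": 500,
    "bin_size": 10,
    "window": 500,
    "trna_window": 200,
    "kmeans_k": 3,
    "kmeans_restarts": 100,
}


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    cfg = {**DEFAULTS, **(config or {})}
    unknown = set(cfg) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim_fields = {f.name for f in dataclasses.fields(sd.SimConfig)}
    bad = set(cfg["sim"]) - sim_fields
    if bad:
        raise ValueError(f"unknown sim config keys: {sorted(bad)}")
    sd.SimConfig(**{**cfg["sim"], "seed": cfg["seed"]}).validate()
    if cfg["sigma"] <= 0 or cfg["exclusion_zone"] < 1:
        raise ValueError("invalid smoothing parameters")
    return cfg


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> dict[str, Any]:
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"parameters": cfg, "stages": []}

    def stage(name: str, outputs: list[str], **info: Any) -> None:
        manifest["stages"].append({"name": name, "outputs": outputs, **info})

    sim_cfg = sd.SimConfig(**{**cfg["sim"], "seed": cfg["seed"]})
    params = pc.SmoothingParams(sigma=cfg["sigma"], exclusion_zone=cfg["exclusion_zone"])

    try:
        annotations = sd.generate_annotations(sim_cfg)
        truth = sd.plant_sites(annotations, sim_cfg)
        chip = {f: sd.simulate_exo_tags(truth, sim_cfg, factor=f, salt=10 + i,
                                        sample=f)
                for i, f in enumerate(sd.FACTORS + ("TBP_tRNA",))}
        input_tags = sd.simulate_input_tags(sim_cfg)
        gio.write_tss_table(annotations.tss_set, outdir / "tss.tsv")
        gio.write_tss_table(annotations.trna_set, outdir / "trna.tsv")
        gio.write_intervals_bed(annotations.cpg_islands, outdir / "cpg_islands.bed")
        gio.write_intervals_bed(annotations.blacklist, outdir / "blacklist.bed")
        gio.write_intervals_bed(annotations.segments, outdir / "segments.bed")
        for f, ds in chip.items():
            gio.write_tags_bed(ds, outdir / f"tags_{f}.bed")
        gio.write_tags_bed(input_tags, outdir / "tags_input.bed")
        stage("simulate", ["tss.tsv", "trna.tsv", "cpg_islands.bed",
                           "blacklist.bed", "segments.bed"],
              n_sites=len(truth.sites))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("simulate", exc) from exc

    try:
        peaks = {f: pc.call_peaks(ds, params) for f, ds in chip.items()}
        stage("callpeaks", [], n_peaks={f: len(v) for f, v in peaks.items()})
    except Exception as exc:
        raise PipelineError("callpeaks", exc) from exc

    try:
        pairs: dict[str, list[pp.PeakPair]] = {}
        for f, pk in peaks.items():
            res = pp.pair_peaks(pk, max_span=cfg["max_span"], sample=f)
            filt = pp.filter_occupancy(
                pp.filter_blacklist(res.pairs, annotations.blacklist),
                min_tags=cfg["min_tags"])
            pairs[f] = filt
            gio.write_peak_pairs(filt, outdir / f"pairs_{f}.tsv")
        stage("pair", [f"pairs_{f}.tsv" for f in pairs],
              n_pairs={f: len(v) for f, v in pairs.items()})
    except Exception as exc:
        raise PipelineError("pair", exc) from exc

    try:
        assignments = {f: ta.assign_to_tss(pairs[f], annotations.tss_set,
                                           max_dist=cfg["tss_max_dist"])
                       for f in sd.FACTORS}
        venn = ta.detection_overlap({"TFIIB": assignments["TFIIB"].genes(),
                                     "TBP": assignments["TBP"].genes(),
                                     "PolII": assignments["PolII"].genes()})
        cpg = ta.cpg_overlap(pairs["TFIIB"], annotations.cpg_islands,
                             assignments["TFIIB"])
        seg_fracs, seg_un = ta.classify_segments(pairs["TFIIB"], annotations.segments)
        summary = {
            "venn": venn,
            "cpg": dataclasses.asdict(cpg),
            "segment_fractions": seg_fracs,
            "segment_unclassified": seg_un,
        }
        (outdir / "annotation_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        stage("annotate", ["annotation_summary.json"],
              n_assigned={f: len(a.assigned) for f, a in assignments.items()})
    except Exception as exc:
        raise PipelineError("annotate", exc) from exc

    try:
        traces = {}
        for f in sd.FACTORS:
            chip_mat = cp.bin_relative_to_tss(chip[f], annotations.tss_set,
                                              bin_size=cfg["bin_size"],
                                              window=cfg["window"])
            input_mat = cp.bin_relative_to_tss(input_tags, annotations.tss_set,
                                               bin_size=cfg["bin_size"],
                                               window=cfg["window"])
            norm = cp.normalize_by_input(chip_mat, input_mat)
            traces[f] = cp.composite_average(norm)
        bins = np.arange(-cfg["window"], cfg["window"], cfg["bin_size"])
        cp.write_composite_trace(bins, traces, outdir / "composites.tsv")
        trna_mode, _ = cp.peak_pair_mode_offset(pairs["TBP_tRNA"],
                                               annotations.trna_set,
                                               max_dist=cfg["trna_window"])
        stage("profile", ["composites.tsv"], trna_mode_offset=int(trna_mode))
    except Exception as exc:
        raise PipelineError("profile", exc) from exc

    try:
        rna = sd.simulate_rna_levels(truth, sim_cfg)
        genes = sorted(truth.gene_occupancy)
        occ_by_gene = {f: {a.gene_id: 0.0 for a in assignments[f].assigned}
                       for f in sd.FACTORS}
        for f in sd.FACTORS:
            for a in assignments[f].assigned:
                occ_by_gene[f][a.gene_id] += a.pair.occupancy
        tables = {"rna": [rna.get(g, 0.0) for g in genes]}
        for f in sd.FACTORS:
            tables[f] = [occ_by_gene[f].get(g, 0.0) for g in genes]
        corr = ostats.pairwise_correlations(tables)
        corr.to_csv(outdir / "correlations.tsv", sep="\t")
        stage("stats", ["correlations.tsv"],
              r_rna_tfiib=float(corr.loc["rna", "TFIIB"]))
    except Exception as exc:
        raise PipelineError("stats", exc) from exc

    try:
        _, truths = sd.simulate_samples(sim_cfg)
        per_sample = {}
        for si, (name, t) in enumerate(sorted(truths.items())):
            tags = sd.simulate_exo_tags(t, sim_cfg, factor="TFIIB",
                                        salt=200 + si, sample=name)
            pk = pc.call_peaks(tags, params)
            res = pp.pair_peaks(pk, max_span=cfg["max_span"], sample=name)
            filt = pp.filter_occupancy(res.pairs, min_tags=cfg["min_tags"])
            per_sample[name] = ta.assign_to_tss(filt, annotations.tss_set,
                                                max_dist=cfg["tss_max_dist"])
        mat = ms.build_matrix(per_sample)
        norm = ms.normalize_columns(mat)
        g1, rest = ms.group_by_detection(norm)
        groups = ms.kmeans_groups(norm, rest, k=cfg["kmeans_k"],
                                  seed=cfg["seed"],
                                  restarts=cfg["kmeans_restarts"]) if rest.size else {}
        dend = ms.cluster_samples(norm)
        (outdir / "dendrogram.nwk").write_text(dend.newick + "\n")
        rows = []
        for i in g1:
            rows.append((norm.gene_ids[i], 1))
        for g, members in sorted(groups.items()):
            rows.extend((norm.gene_ids[i], g) for i in members)
        with open(outdir / "groups.tsv", "w") as fh:
            fh.write("gene\tgroup\n")
            for gene, g in rows:
                fh.write(f"{gene}\t{g}\n")
        stage("multisample", ["groups.tsv", "dendrogram.nwk"],
              n_group1=int(g1.size), leaf_order=dend.leaf_order)
    except Exception as exc:
        raise PipelineError("multisample", exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
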