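"""Assign the filtered TFIIB/TBP/Pol II locations from step 02 to TSSs
(within 500 bp), compute the factor-detection Venn, CpG-island occupancy
(complexes per island, island coverage of occupied promoters) and the
genome-segment class breakdown."""

import json

from _common import TSS_MAX_DIST, outdir

from exopair import genome_io as gio
from exopair.synthetic_data import FACTORS
from exopair.tss_annotation import (assign_to_tss, classify_segments, cpg_overlap,
                                    detection_overlap)


def main() -> None:
    out = outdir()
    tss = gio.read_tss_table(out / "tss.tsv")
    islands = gio.read_intervals_bed(out / "cpg_islands.bed")
    segments = gio.read_intervals_bed(out / "segments.bed")
    assignments, sets = {}, {}
    for factor in FACTORS:
        pairs = gio.read_peak_pairs(out / f"pairs_{factor}.tsv")
        assignments[factor] = assign_to_tss(pairs, tss, max_dist=TSS_MAX_DIST)
        sets[factor] = assignments[factor].genes()
        print(f"{factor}: {len(assignments[factor].assigned)} TSS-proximal, "
              f"{len(assignments[factor].distal)} distal locations; "
              f"{len(sets[factor])} genes")
    venn = detection_overlap(sets)
    tfiib_pairs = [a.pair for a in assignments["TFIIB"].assigned] + \
        assignments["TFIIB"].distal
    cpg = cpg_overlap(tfiib_pairs, islands, assignments["TFIIB"])
    seg_fracs, seg_un = classify_segments(tfiib_pairs, segments)
    summary = {
        "venn": venn,
        "cpg": {"islands_occupied": cpg.n_islands_occupied,
                "locations_in_islands": cpg.n_locations_in_islands,
                "mean_per_occupied_island": cpg.mean_per_occupied_island,
                "fraction_genes_with_island_location":
                    cpg.fraction_genes_with_island_location},
        "segment_fractions": seg_fracs,
        "segment_unclassified": seg_un,
    }
    (out / "annotation_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    print(f"three-factor intersection: {venn['PolII&TBP&TFIIB']} genes "
          f"of {venn['union']} detected in any factor")
    print(f"CpG islands: {cpg.mean_per_occupied_island:.2f} complexes per "
          f"occupied island; {100 * cpg.fraction_genes_with_island_location:.0f}% "
          "of TFIIB genes have an island-resident location")


if __name__ == "__main__":
    main()
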