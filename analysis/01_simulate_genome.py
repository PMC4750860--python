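"""Generate the synthetic study: a miniature genome annotation with planted
TBP/TFIIB/Pol II complexes (plus TBP at tRNA genes), divergent partner
complexes at half the genes, exo-border tag datasets per factor and a
uniform Input dataset."""

from _common import SIM, outdir

from exopair import genome_io as gio
from exopair.synthetic_data import (FACTORS, generate_annotations, plant_sites,
                                    simulate_exo_tags, simulate_input_tags)


def main() -> None:
    out = outdir()
    ann = generate_annotations(SIM)
    truth = plant_sites(ann, SIM)
    gio.write_tss_table(ann.tss_set, out / "tss.tsv")
    gio.write_tss_table(ann.trna_set, out / "trna.tsv")
    gio.write_intervals_bed(ann.cpg_islands, out / "cpg_islands.bed")
    gio.write_intervals_bed(ann.blacklist, out / "blacklist.bed")
    gio.write_intervals_bed(ann.segments, out / "segments.bed")
    for i, factor in enumerate(FACTORS + ("TBP_tRNA",)):
        tags = simulate_exo_tags(truth, SIM, factor=factor, salt=10 + i,
                                 sample=factor)
        gio.write_tags_bed(tags, out / f"tags_{factor}.bed")
        print(f"{factor}: {tags.total} tags")
    gio.write_tags_bed(simulate_input_tags(SIM), out / "tags_input.bed")
    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write("factor\tchrom\tmidpoint\tstrand\toccupancy\tgene\tclass\n")
        for s in truth.sites:
            fh.write(f"{s.factor}\t{s.chrom}\t{s.midpoint}\t{s.strand}\t"
                     f"{s.occupancy}\t{s.gene_id}\t{s.site_class}\n")
    n_div = sum(1 for s in truth.sites if s.site_class == "divergent") // len(FACTORS)
    print(f"planted {len(truth.sites)} sites at {len(ann.tss_set)} genes "
          f"({n_div} with divergent partners) and {len(ann.trna_set)} tRNA genes")


if __name__ == "__main__":
    main()
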