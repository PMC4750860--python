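"""Cross-"cell-line" occupancy: simulate the pseudo-sample panel, call and
pair TFIIB per sample, build the gene x sample occupancy matrix, split off
the detected-everywhere Group 1, k-means the remainder into Groups 2-4, and
cluster the samples into a dendrogram."""

from _common import MAX_SPAN, MIN_TAGS, PARAMS, SIM, TSS_MAX_DIST, outdir

from exopair.multi_sample import (build_matrix, cluster_samples,
                                  group_by_detection, kmeans_groups,
                                  normalize_columns)
from exopair.peak_calling import call_peaks
from exopair.peak_pairing import filter_occupancy, pair_peaks
from exopair.synthetic_data import simulate_exo_tags, simulate_samples
from exopair.tss_annotation import assign_to_tss


def main() -> None:
    out = outdir()
    ann, truths = simulate_samples(SIM)
    per_sample = {}
    for si, (name, truth) in enumerate(sorted(truths.items())):
        tags = simulate_exo_tags(truth, SIM, factor="TFIIB", salt=200 + si,
                                 sample=name)
        peaks = call_peaks(tags, PARAMS)
        pairs = filter_occupancy(pair_peaks(peaks, max_span=MAX_SPAN,
                                            sample=name).pairs,
                                 min_tags=MIN_TAGS)
        per_sample[name] = assign_to_tss(pairs, ann.tss_set,
                                         max_dist=TSS_MAX_DIST)
        print(f"{name}: {len(per_sample[name].genes())} genes detected")
    mat = build_matrix(per_sample)
    norm = normalize_columns(mat)
    g1, rest = group_by_detection(norm)
    groups = kmeans_groups(norm, rest, k=3, seed=SIM.seed, restarts=100)
    print(f"{len(mat.gene_ids)} genes in the matrix; Group 1 "
          f"(all {len(mat.samples)} samples): {g1.size} genes; "
          + "; ".join(f"Group {g}: {m.size}" for g, m in sorted(groups.items())))
    with open(out / "groups.tsv", "w") as fh:
        fh.write("gene\tgroup\n")
        for i in g1:
            fh.write(f"{norm.gene_ids[i]}\t1\n")
        for g, members in sorted(groups.items()):
            for i in members:
                fh.write(f"{norm.gene_ids[i]}\t{g}\n")
    dend = cluster_samples(norm)
    (out / "dendrogram.nwk").write_text(dend.newick + "\n")
    print(f"sample dendrogram leaf order: {' '.join(dend.leaf_order)}")
    print(f"newick: {dend.newick}")


if __name__ == "__main__":
    main()
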