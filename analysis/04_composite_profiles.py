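"""Build TSS-aligned composites: bin each factor's tags in 10-bp intervals
around the TSS, normalize by Input RPKM, average as percent of total, and
locate the modal peak-pair offsets (TFIIB/TBP upstream, paused Pol II
downstream, TBP ~21 bp upstream of tRNA TSSs)."""

import numpy as np
from _common import SIM, outdir

from exopair import genome_io as gio
from exopair.composite_profiles import (bin_relative_to_tss, composite_average,
                                        peak_pair_mode_offset,
                                        write_composite_trace)
from exopair.synthetic_data import FACTORS


def main() -> None:
    out = outdir()
    tss = gio.read_tss_table(out / "tss.tsv")
    trna = gio.read_tss_table(out / "trna.tsv")
    input_tags = gio.read_tags_bed(out / "tags_input.bed", sample="input")
    input_mat = bin_relative_to_tss(input_tags, tss, bin_size=10, window=500)
    traces = {}
    for factor in FACTORS:
        tags = gio.read_tags_bed(out / f"tags_{factor}.bed", sample=factor)
        mat = bin_relative_to_tss(tags, tss, bin_size=10, window=500)
        from exopair.composite_profiles import normalize_by_input
        traces[factor] = composite_average(normalize_by_input(mat, input_mat))
        pairs = gio.read_peak_pairs(out / f"pairs_{factor}.tsv")
        mode, _ = peak_pair_mode_offset(pairs, tss)
        peak_bin = int(np.arange(-500, 500, 10)[int(np.argmax(traces[factor]))])
        print(f"{factor}: composite maximum in bin [{peak_bin},{peak_bin + 10}); "
              f"modal peak-pair offset {mode:+d} bp")
    write_composite_trace(np.arange(-500, 500, 10), traces,
                          out / "composites.tsv")
    trna_pairs = gio.read_peak_pairs(out / "pairs_TBP_tRNA.tsv")
    mode, hist = peak_pair_mode_offset(trna_pairs, trna, max_dist=200)
    print(f"TBP at tRNA genes: modal offset {mode:+d} bp "
          f"({hist.get(mode, 0)} of {sum(hist.values())} locations)")


if __name__ == "__main__":
    main()
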