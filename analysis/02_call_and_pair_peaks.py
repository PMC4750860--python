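"""Call strand-separated peaks (Gaussian sigma 20, exclusion zone 40 bp) on
each factor's tags from step 01, pair W/C peaks within 0-80 bp, drop
blacklisted midpoints and pairs with <= 4 tags, and report how well the
surviving locations recover the planted crosslink points."""

import numpy as np
from _common import MAX_SPAN, MIN_TAGS, PARAMS, outdir

from exopair import genome_io as gio
from exopair.peak_calling import call_peaks
from exopair.peak_pairing import filter_blacklist, filter_occupancy, pair_peaks
from exopair.synthetic_data import FACTORS


def main() -> None:
    out = outdir()
    blacklist = gio.read_intervals_bed(out / "blacklist.bed")
    truth_mids = {}
    with open(out / "ground_truth.tsv") as fh:
        fh.readline()
        for line in fh:
            factor, chrom, mid, *_ = line.split("\t")
            truth_mids.setdefault(factor, []).append((chrom, int(mid)))
    for factor in FACTORS + ("TBP_tRNA",):
        tags = gio.read_tags_bed(out / f"tags_{factor}.bed", sample=factor)
        peaks = call_peaks(tags, PARAMS)
        res = pair_peaks(peaks, max_span=MAX_SPAN, sample=factor)
        pairs = filter_occupancy(filter_blacklist(res.pairs, blacklist),
                                 min_tags=MIN_TAGS)
        gio.write_peak_pairs(pairs, out / f"pairs_{factor}.tsv")
        mids = {}
        for p in pairs:
            mids.setdefault(p.chrom, []).append(p.midpoint)
        mids = {c: np.sort(v) for c, v in mids.items()}
        hit = 0
        for chrom, x in truth_mids[factor]:
            arr = mids.get(chrom, np.empty(0))
            i = int(np.searchsorted(arr, x))
            hit += any(0 <= k < arr.size and abs(int(arr[k]) - x) <= 5
                       for k in (i - 1, i))
        n = len(truth_mids[factor])
        print(f"{factor}: {len(peaks)} peaks -> {len(pairs)} filtered pairs; "
              f"{100 * hit / n:.1f}% of {n} planted sites recovered within 5 bp")


if __name__ == "__main__":
    main()
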