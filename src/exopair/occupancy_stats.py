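"""Inter-complex distance statistics, sliding-window variability, and
occupancy/expression correlation analyses.

All log2 transforms use a +1 pseudocount; medians are computed over the genes
entering the analysis. Standard deviations are the sample (n-1) form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class AdjacentRecord:
    distance: int
    left_occupancy: float
    right_occupancy: float


def inter_location_distances(groups: Mapping[str, Sequence[tuple[int, float]]]) -> list[AdjacentRecord]:
    """Within each group (island/promoter), sort locations by coordinate and
    emit one record per *adjacent* pair: (distance, left occ, right occ)."""
    out: list[AdjacentRecord] = []
    for key in sorted(groups):
        locs = sorted(groups[key])
        for (x1, o1), (x2, o2) in zip(locs, locs[1:]):
            out.append(AdjacentRecord(x2 - x1, o1, o2))
    return out


def sliding_window_sd(records: Sequence[AdjacentRecord], window: int = 30) -> list[tuple[float, float]]:
    """Variability of occupancy between adjacent complexes versus their spacing.

    Records are stably sorted by distance; a window of ``window`` consecutive
    records slides with step 1; each point is (median distance in window,
    sample SD of the within-pair occupancy difference right - left). Adjacent
    complexes with coordinated occupancy give near-zero differences, hence a
    low SD; independently regulated complexes give an SD near sqrt(2) times
    the between-site spread — so the trace localizes the spacing beyond which
    occupancies decouple.
    """
    if len(records) < window:
        raise ValueError(f"need >= {window} records, got {len(records)}")
    recs = sorted(records, key=lambda r: r.distance)  # stable for ties
    out = []
    for i in range(len(recs) - window + 1):
        chunk = recs[i:i + window]
        diffs = [r.right_occupancy - r.left_occupancy for r in chunk]
        out.append((float(np.median([r.distance for r in chunk])),
                    float(np.std(diffs, ddof=1))))
    return out


def adjacent_occupancy_correlation(records: Sequence[AdjacentRecord],
                                   strata: Sequence[tuple[int, int]]) -> dict[tuple[int, int], tuple[float | None, int]]:
    """Pearson r between left and right occupancies within each half-open
    distance stratum [lo, hi); r is None where n < 3."""
    out: dict[tuple[int, int], tuple[float | None, int]] = {}
    for lo, hi in strata:
        sub = [r for r in records if lo <= r.distance < hi]
        n = len(sub)
        if n < 3:
            out[(lo, hi)] = (None, n)
            continue
        left = [r.left_occupancy for r in sub]
        right = [r.right_occupancy for r in sub]
        if np.std(left) == 0 or np.std(right) == 0:
            out[(lo, hi)] = (None, n)
            continue
        out[(lo, hi)] = (float(sps.pearsonr(left, right)[0]), n)
    return out


def _log2_center(values: np.ndarray) -> np.ndarray:
    lv = np.log2(np.asarray(values, dtype=float) + 1.0)
    return lv - np.median(lv)


def moving_average_trend(x: Sequence[float], y: Sequence[float],
                         window: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Genes sorted by x; windowed means (step 1) of median-centered
    log2(v+1) for both series. Mirrors the ranked moving-average display of
    expression versus occupancy."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must align gene-by-gene")
    if window > x.size:
        raise ValueError("window larger than the number of genes")
    xl, yl = _log2_center(x), _log2_center(y)
    order = np.argsort(xl, kind="stable")
    xl, yl = xl[order], yl[order]
    kernel = np.ones(window) / window
    return (np.convolve(xl, kernel, mode="valid"),
            np.convolve(yl, kernel, mode="valid"))


def pairwise_correlations(tables: Mapping[str, Sequence[float]]) -> "pd.DataFrame":
    """All-vs-all Pearson r on median-centered log2(v+1) values; for each
    pair of series, genes with a zero in either series are excluded."""
    import pandas as pd

    names = list(tables)
    arrays = {n: np.asarray(tables[n], float) for n in names}
    sizes = {a.size for a in arrays.values()}
    if len(sizes) != 1:
        raise ValueError("all series must align gene-by-gene")
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            keep = (arrays[a] > 0) & (arrays[b] > 0)
            if keep.sum() < 3:
                val = np.nan
            else:
                val = sps.pearsonr(_log2_center(arrays[a][keep]),
                                   _log2_center(arrays[b][keep]))[0]
            r.loc[a, b] = r.loc[b, a] = val
    return r
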