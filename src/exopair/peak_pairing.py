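"""Pairing of W/C strand peaks into bound locations, plus the standard filters.

A W (forward) peak at ``w`` may pair with a C (reverse) peak at ``c`` iff
``0 <= c - w <= max_span`` — the C border must sit 0–80 bp in the 3'
direction of the W border, because exonuclease borders flank the protected
footprint with the W border to the left. Each peak joins at most one pair;
conflicts are resolved smallest span first, then larger combined tag count,
then leftmost W summit. The pair midpoint estimates the protein-DNA
crosslink point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import C, IntervalSet, W
from .peak_calling import Peak


@dataclass(frozen=True)
class PeakPair:
    chrom: str
    w_summit: int
    c_summit: int
    occupancy: int
    sample: str = "sample"

    def __post_init__(self) -> None:
        if self.c_summit < self.w_summit:
            raise ValueError("C summit must not be 5' of W summit")

    @property
    def midpoint(self) -> int:
        return (self.w_summit + self.c_summit) // 2

    @property
    def span(self) -> int:
        return self.c_summit - self.w_summit


@dataclass
class PairingResult:
    pairs: list[PeakPair]
    unpaired_w: list[Peak] = field(default_factory=list)
    unpaired_c: list[Peak] = field(default_factory=list)


def pair_peaks_chrom(w_peaks: list[Peak], c_peaks: list[Peak],
                     max_span: int = 80, sample: str = "sample") -> PairingResult:
    """Pair peaks from one chromosome.

    Candidate (W, C) couples with span in [0, max_span] are taken greedily in
    order (span, -combined tag_count, w summit); a peak already used is
    skipped. This favors the tightest footprints.
    """
    chroms = {p.chrom for p in w_peaks} | {p.chrom for p in c_peaks}
    if len(chroms) > 1:
        raise ValueError(f"mixed chromosomes in one pairing call: {sorted(chroms)}")
    cands = []
    for i, wp in enumerate(w_peaks):
        for j, cp in enumerate(c_peaks):
            span = cp.summit - wp.summit
            if 0 <= span <= max_span:
                cands.append((span, -(wp.tag_count + cp.tag_count), wp.summit, i, j))
    cands.sort()
    used_w: set[int] = set()
    used_c: set[int] = set()
    pairs: list[PeakPair] = []
    for _span, _negocc, _w, i, j in cands:
        if i in used_w or j in used_c:
            continue
        used_w.add(i)
        used_c.add(j)
        wp, cp = w_peaks[i], c_peaks[j]
        pairs.append(PeakPair(wp.chrom, wp.summit, cp.summit,
                              wp.tag_count + cp.tag_count, sample))
    pairs.sort(key=lambda p: p.w_summit)
    return PairingResult(
        pairs=pairs,
        unpaired_w=[p for i, p in enumerate(w_peaks) if i not in used_w],
        unpaired_c=[p for j, p in enumerate(c_peaks) if j not in used_c],
    )


def pair_peaks(peaks: list[Peak], max_span: int = 80,
               sample: str = "sample") -> PairingResult:
    """Pair a mixed peak list, chromosome by chromosome."""
    by_chrom: dict[str, tuple[list[Peak], list[Peak]]] = {}
    for p in peaks:
        ws, cs = by_chrom.setdefault(p.chrom, ([], []))
        (ws if p.strand == W else cs).append(p)
    result = PairingResult(pairs=[])
    for chrom in sorted(by_chrom):
        ws, cs = by_chrom[chrom]
        r = pair_peaks_chrom(sorted(ws, key=lambda p: p.summit),
                             sorted(cs, key=lambda p: p.summit),
                             max_span=max_span, sample=sample)
        result.pairs.extend(r.pairs)
        result.unpaired_w.extend(r.unpaired_w)
        result.unpaired_c.extend(r.unpaired_c)
    return result


def filter_blacklist(pairs: list[PeakPair], blacklist: IntervalSet) -> list[PeakPair]:
    """Drop pairs whose midpoint falls inside a blacklist interval (half-open)."""
    return [p for p in pairs if not blacklist.contains_point(p.chrom, p.midpoint)]


def filter_occupancy(pairs: list[PeakPair], min_tags: int = 4) -> list[PeakPair]:
    """Keep pairs with occupancy strictly greater than ``min_tags``."""
    return [p for p in pairs if p.occupancy > min_tags]


def match_locations(pairs_a: list[PeakPair], pairs_b: list[PeakPair],
                    window: int) -> tuple[list[PeakPair], list[PeakPair]]:
    """Split A into (matched, unmatched): a location matches iff some B
    midpoint on the same chromosome lies within <= window bp of its midpoint."""
    import numpy as np

    b_by_chrom: dict[str, np.ndarray] = {}
    for p in pairs_b:
        b_by_chrom.setdefault(p.chrom, [])
    for p in pairs_b:
        b_by_chrom[p.chrom].append(p.midpoint)  # type: ignore[union-attr]
    b_sorted = {c: np.sort(np.asarray(v)) for c, v in b_by_chrom.items()}
    matched, unmatched = [], []
    for p in pairs_a:
        mids = b_sorted.get(p.chrom)
        hit = False
        if mids is not None and mids.size:
            i = int(np.searchsorted(mids, p.midpoint))
            for k in (i - 1, i):
                if 0 <= k < mids.size and abs(int(mids[k]) - p.midpoint) <= window:
                    hit = True
                    break
        (matched if hit else unmatched).append(p)
    return matched, unmatched
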