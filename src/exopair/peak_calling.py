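"""Strand-separated Gaussian-kernel peak caller with an exclusion zone.

Tag 5' ends on each strand are smoothed with an un-normalized Gaussian kernel
(sum of Gaussians, sigma in bp, truncated at ``truncation``·sigma). Candidate
summits are strict local maxima of the smoothed density; they are retained
greedily in descending height, and a candidate is discarded if its summit lies
within ``exclusion_zone`` bp (center-to-center) of an already-retained summit
on the same strand. The exclusion zone therefore bounds the resolution at
which two adjacent binding locations can be distinguished.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .genome_io import TagDataset


@dataclass(frozen=True)
class SmoothingParams:
    sigma: float = 20.0
    truncation: float = 4.0  # kernel support = +/- truncation*sigma
    exclusion_zone: int = 40

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.exclusion_zone < 1:
            raise ValueError("exclusion_zone must be >= 1")

    @property
    def half_support(self) -> int:
        return int(np.ceil(self.truncation * self.sigma))


@dataclass(frozen=True)
class Peak:
    chrom: str
    strand: str
    summit: int
    height: float
    tag_count: int


@dataclass(frozen=True)
class DensityTrack:
    """Smoothed density over [start, start+len(values)) at integer bp."""

    start: int
    values: np.ndarray

    def at(self, pos: int) -> float:
        i = pos - self.start
        if 0 <= i < self.values.size:
            return float(self.values[i])
        return 0.0


def _kernel(params: SmoothingParams) -> np.ndarray:
    h = params.half_support
    x = np.arange(-h, h + 1, dtype=float)
    return np.exp(-(x ** 2) / (2.0 * params.sigma ** 2))


def smooth_strand(coords: np.ndarray, params: SmoothingParams) -> DensityTrack | None:
    """Density(p) = sum over tags t of exp(-(p-t)^2 / (2 sigma^2)).

    Evaluated at every integer bp within kernel support of any tag; positions
    further away are exactly zero because the kernel is truncated.
    """
    if coords.size == 0:
        return None
    h = params.half_support
    lo = int(coords.min()) - h
    hi = int(coords.max()) + h
    # every nonzero count sits >= h from both array edges, so mode="same" is exact
    counts = np.bincount(coords - lo, minlength=hi - lo + 1).astype(float)
    dens = np.convolve(counts, _kernel(params), mode="same")
    return DensityTrack(start=lo, values=dens)


def smooth_tags(tags: TagDataset, params: SmoothingParams) -> dict[tuple[str, str], DensityTrack]:
    """Per-(chrom, strand) smoothed density for every strand with >=1 tag."""
    out = {}
    for key, coords in tags.items():
        track = smooth_strand(coords, params)
        if track is not None:
            out[key] = track
    return out


_REL_TOL = 1e-9  # densities this close are ties (plateau); leftmost wins


def _approx_eq(a: float, b: float) -> bool:
    return abs(a - b) <= _REL_TOL * max(abs(a), abs(b))


def _local_maxima(track: DensityTrack) -> list[tuple[int, float]]:
    """Local maxima; a plateau (values tied within _REL_TOL) counts once, at
    its leftmost position. The tolerance makes the summit well-defined when
    the continuous maximum falls halfway between integer positions."""
    v = track.values
    n = v.size
    out: list[tuple[int, float]] = []
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1] and not _approx_eq(v[i], v[i - 1]):
            j = i
            while j + 1 < n and _approx_eq(v[j + 1], v[i]):
                j += 1
            if j + 1 >= n or v[j + 1] < v[i]:
                out.append((track.start + i, float(v[i])))
            i = j + 1
        else:
            i += 1
    return out


def call_peaks_strand(coords: np.ndarray, chrom: str, strand: str,
                      params: SmoothingParams,
                      track: DensityTrack | None = None) -> list[Peak]:
    """Greedy exclusion-zone selection on one strand.

    Candidates ordered by descending height, ties broken leftmost; a candidate
    within < exclusion_zone of a retained summit is dropped. ``tag_count`` is
    the number of raw tags in [summit - ez/2, summit + ez/2].
    """
    if coords.size == 0:
        return []
    if track is None:
        track = smooth_strand(coords, params)
    cands = _local_maxima(track)
    # heights quantized for ordering so ties resolve leftmost reproducibly
    cands.sort(key=lambda sh: (-round(sh[1], 6), sh[0]))
    retained: list[int] = []  # sorted summits
    peaks: list[Peak] = []
    ez = params.exclusion_zone
    half = ez // 2
    for summit, height in cands:
        i = bisect.bisect_left(retained, summit)
        if i > 0 and summit - retained[i - 1] < ez:
            continue
        if i < len(retained) and retained[i] - summit < ez:
            continue
        bisect.insort(retained, summit)
        lo = np.searchsorted(coords, summit - half, side="left")
        hi = np.searchsorted(coords, summit + half, side="right")
        tag_count = int(hi - lo)
        if tag_count >= 1:
            peaks.append(Peak(chrom, strand, summit, height, tag_count))
    peaks.sort(key=lambda p: p.summit)
    return peaks


def call_peaks(tags: TagDataset, params: SmoothingParams | None = None,
               density: dict[tuple[str, str], DensityTrack] | None = None) -> list[Peak]:
    """Call peaks on every (chrom, strand) of the dataset."""
    params = params or SmoothingParams()
    if density is None:
        density = smooth_tags(tags, params)
    peaks: list[Peak] = []
    for (chrom, strand), coords in tags.items():
        peaks.extend(call_peaks_strand(coords, chrom, strand, params,
                                       track=density.get((chrom, strand))))
    peaks.sort(key=lambda p: (p.chrom, p.strand, p.summit))
    return peaks


def merge_replicates(tagsets: list[TagDataset], sample: str | None = None) -> TagDataset:
    """Coordinate-wise multiset union of replicate tag datasets."""
    merged = TagDataset(sample=sample or (tagsets[0].sample if tagsets else "merged"))
    for ds in tagsets:
        for (chrom, strand), coords in ds.items():
            merged.add_tags(chrom, strand, coords)
    return merged
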