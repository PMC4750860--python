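"""TSS-aligned composite profiles and per-gene heatmap matrices.

Signal (tag 5' ends or peak-pair midpoints) is binned in non-overlapping
fixed-width intervals relative to each gene's TSS, with offsets oriented by
gene strand (upstream negative). ChIP matrices can be normalized bin-wise by
an Input matrix on the RPKM scale, and composites are reported as a percent
of total so traces are comparable across factors with different sequencing
depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import C, TagDataset, TssRecord, W
from .peak_pairing import PeakPair


@dataclass
class ProfileMatrix:
    """rows: genes; columns: offset bins [-window, window) of width ``bin_size``."""

    gene_ids: list[str]
    values: np.ndarray          # (n_genes, n_bins) float
    bin_size: int
    window: int
    total_tags: int             # depth of the source dataset (both strands)
    missing: np.ndarray | None = None  # bool mask, True where bin is undefined
    row_order: np.ndarray | None = None  # permutation, never applied destructively

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(-self.window, self.window, self.bin_size)

    @property
    def n_bins(self) -> int:
        return 2 * self.window // self.bin_size


def _oriented_offset(pos: int, tss: int, strand: str) -> int:
    return pos - tss if strand == "+" else tss - pos


def bin_relative_to_tss(signal: TagDataset | Iterable[PeakPair],
                        tss_set: Mapping[str, TssRecord],
                        bin_size: int = 10, window: int = 500,
                        tss_choice: Mapping[str, int] | None = None,
                        strand_split: bool = False):
    """Accumulate signal into per-gene offset bins.

    ``tss_choice`` optionally fixes one TSS per gene (e.g. the primary TSS
    from assignment); otherwise the first annotated TSS is used. With
    ``strand_split`` a TagDataset yields two matrices keyed "same"/"opposite"
    (tag strand relative to the gene strand); peak-pair input yields one
    matrix of midpoint counts.
    """
    if 2 * window % bin_size:
        raise ValueError("window must be a whole number of bins")
    genes = sorted(tss_set)
    n_bins = 2 * window // bin_size
    gene_index = {g: i for i, g in enumerate(genes)}

    def new_mat(total: int) -> ProfileMatrix:
        return ProfileMatrix(list(genes), np.zeros((len(genes), n_bins)),
                             bin_size, window, total)

    def accumulate(mat: ProfileMatrix, gene: str, offset: int) -> None:
        if -window <= offset < window:
            b = (offset + window) // bin_size
            mat.values[gene_index[gene], b] += 1

    if isinstance(signal, TagDataset):
        same = new_mat(signal.total)
        opp = new_mat(signal.total)
        for gene in genes:
            rec = tss_set[gene]
            tss = tss_choice[gene] if tss_choice else rec.positions[0]
            lo, hi = tss - window - 1, tss + window + 1
            for strand in (W, C):
                coords = signal.tags(rec.chrom, strand)
                i0 = np.searchsorted(coords, lo)
                i1 = np.searchsorted(coords, hi)
                tag_strand = "+" if strand == W else "-"
                mat = same if tag_strand == rec.strand else opp
                for pos in coords[i0:i1]:
                    accumulate(mat, gene, _oriented_offset(int(pos), tss, rec.strand))
        if strand_split:
            return {"same": same, "opposite": opp}
        combined = new_mat(signal.total)
        combined.values = same.values + opp.values
        return combined

    pairs = list(signal)
    mat = new_mat(len(pairs))
    by_chrom: dict[str, list[PeakPair]] = {}
    for p in pairs:
        by_chrom.setdefault(p.chrom, []).append(p)
    for gene in genes:
        rec = tss_set[gene]
        tss = tss_choice[gene] if tss_choice else rec.positions[0]
        for p in by_chrom.get(rec.chrom, []):
            accumulate(mat, gene, _oriented_offset(p.midpoint, tss, rec.strand))
    return mat


def _rpkm(mat: ProfileMatrix) -> np.ndarray:
    if mat.total_tags <= 0:
        raise ValueError("RPKM undefined for an empty dataset")
    bin_kb = mat.bin_size / 1000.0
    millions = mat.total_tags / 1e6
    return mat.values / (bin_kb * millions)


def normalize_by_input(chip: ProfileMatrix, input_: ProfileMatrix) -> ProfileMatrix:
    """Bin-wise ChIP RPKM / Input RPKM; bins with zero Input are marked
    missing (excluded from composites) rather than infinite."""
    if (chip.bin_size, chip.window, chip.gene_ids) != (input_.bin_size, input_.window, input_.gene_ids):
        raise ValueError("mismatched bin structure between ChIP and Input matrices")
    chip_rpkm = _rpkm(chip)
    input_rpkm = _rpkm(input_)
    missing = input_rpkm == 0
    out = np.zeros_like(chip_rpkm)
    np.divide(chip_rpkm, input_rpkm, out=out, where=~missing)
    return ProfileMatrix(list(chip.gene_ids), out, chip.bin_size, chip.window,
                         chip.total_tags, missing=missing)


def composite_average(matrix: ProfileMatrix) -> np.ndarray:
    """Per-bin mean over genes (missing bins excluded), scaled to sum to 100."""
    if matrix.missing is not None:
        masked = np.ma.masked_array(matrix.values, mask=matrix.missing)
        trace = masked.mean(axis=0).filled(0.0)
    else:
        trace = matrix.values.mean(axis=0)
    total = trace.sum()
    if total == 0:
        return np.zeros_like(trace)
    return 100.0 * trace / total


def sort_rows(keys: Sequence[float]) -> np.ndarray:
    """Stable row order by a per-gene key; apply the SAME permutation to every
    linked matrix so rows stay aligned across factors."""
    return np.argsort(np.asarray(keys), kind="stable")


def apply_row_order(matrix: ProfileMatrix, order: np.ndarray) -> ProfileMatrix:
    return ProfileMatrix([matrix.gene_ids[i] for i in order],
                         matrix.values[order], matrix.bin_size, matrix.window,
                         matrix.total_tags,
                         missing=None if matrix.missing is None else matrix.missing[order],
                         row_order=order)


def peak_pair_mode_offset(pairs: Iterable[PeakPair],
                          tss_set: Mapping[str, TssRecord],
                          max_dist: int = 500) -> tuple[int, dict[int, int]]:
    """Histogram of strand-oriented midpoint offsets at 1-bp resolution and
    its mode (ties broken to the smallest |offset|)."""
    from .tss_annotation import assign_to_tss

    result = assign_to_tss(list(pairs), tss_set, max_dist=max_dist)
    if not result.assigned:
        raise ValueError("no pairs within range of any TSS")
    hist: dict[int, int] = {}
    for a in result.assigned:
        hist[a.offset] = hist.get(a.offset, 0) + 1
    mode = min(hist, key=lambda k: (-hist[k], abs(k), k))
    return mode, dict(sorted(hist.items()))


def write_profile_matrix(matrix: ProfileMatrix, path) -> None:
    import pandas as pd

    df = pd.DataFrame(matrix.values, index=matrix.gene_ids,
                      columns=[str(b) for b in matrix.bin_starts])
    df.to_csv(path, sep="\t", index_label="gene")


def write_composite_trace(bin_starts: np.ndarray, traces: Mapping[str, np.ndarray], path) -> None:
    import pandas as pd

    df = pd.DataFrame({"bin_start": bin_starts, **{k: v for k, v in traces.items()}})
    df.to_csv(path, sep="\t", index=False)
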