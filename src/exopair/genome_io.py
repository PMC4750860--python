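"""Readers/writers for the formats the pipeline touches, and the core tag container.

All coordinates are 0-based half-open internally (BED-native). SAM's 1-based
POS is converted on ingest. Strands are named W (Watson, forward, ``+``) and
C (Crick, reverse, ``-``) throughout; a tag is the 5' end of a sequenced read,
which for a reverse-strand read is its *right* edge.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from intervaltree import IntervalTree

W = "W"
C = "C"

_STRAND_TO_WC = {"+": W, "-": C, W: W, C: C}


class TagDataset:
    """Per-(chromosome, strand) multiset of 5'-end tag coordinates.

    Coordinates are stored as sorted int64 arrays with repeats for
    multiplicity. This is the raw signal every downstream stage consumes.
    """

    def __init__(self, sample: str = "sample") -> None:
        self.sample = sample
        self._tags: dict[tuple[str, str], np.ndarray] = {}

    def add_tags(self, chrom: str, strand: str, coords: Iterable[int]) -> None:
        strand = _STRAND_TO_WC[strand]
        new = np.asarray(list(coords) if not isinstance(coords, np.ndarray) else coords,
                         dtype=np.int64)
        if new.size and new.min() < 0:
            raise ValueError("tag coordinates must be non-negative")
        key = (chrom, strand)
        if key in self._tags:
            new = np.concatenate([self._tags[key], new])
        self._tags[key] = np.sort(new)

    def tags(self, chrom: str, strand: str) -> np.ndarray:
        return self._tags.get((chrom, _STRAND_TO_WC[strand]), np.empty(0, dtype=np.int64))

    def chroms(self) -> list[str]:
        return sorted({c for c, _ in self._tags})

    @property
    def total(self) -> int:
        return sum(a.size for a in self._tags.values())

    def items(self) -> Iterator[tuple[tuple[str, str], np.ndarray]]:
        return iter(sorted(self._tags.items()))

    def counts(self) -> dict[tuple[str, str, int], int]:
        """Multiplicity per (chrom, strand, coord) — mainly for round-trip tests."""
        out: dict[tuple[str, str, int], int] = defaultdict(int)
        for (chrom, strand), arr in self._tags.items():
            coords, mult = np.unique(arr, return_counts=True)
            for c, m in zip(coords, mult):
                out[(chrom, strand, int(c))] = int(m)
        return dict(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TagDataset):
            return NotImplemented
        if set(self._tags) != set(other._tags):
            return False
        return all(np.array_equal(self._tags[k], other._tags[k]) for k in self._tags)


@dataclass
class TssRecord:
    """A gene with one or more annotated TSSs on a single strand."""

    gene_id: str
    chrom: str
    strand: str
    positions: list[int] = field(default_factory=list)


class IntervalSet:
    """Labeled genomic intervals with point and overlap queries (half-open)."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._order = 0

    def add(self, chrom: str, start: int, end: int, label: str = "") -> None:
        if not start < end:
            raise ValueError(f"interval start must be < end: [{start}, {end})")
        # data carries (insertion order, label) so "first by file order" is decidable
        self._trees[chrom].addi(start, end, (self._order, label))
        self._order += 1

    def query_point(self, chrom: str, pos: int) -> list[tuple[int, int, str]]:
        hits = sorted(self._trees[chrom].at(pos), key=lambda iv: iv.data[0])
        return [(iv.begin, iv.end, iv.data[1]) for iv in hits]

    def contains_point(self, chrom: str, pos: int) -> bool:
        return bool(self._trees[chrom].at(pos))

    def first_label_at(self, chrom: str, pos: int) -> str | None:
        hits = self.query_point(chrom, pos)
        return hits[0][2] if hits else None

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __iter__(self) -> Iterator[tuple[str, int, int, str]]:
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield chrom, iv.begin, iv.end, iv.data[1]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_tags_bed(path: str | Path, sample: str | None = None) -> TagDataset:
    """Load 5'-end tags from BED6: start for ``+`` records, end-1 for ``-``."""
    path = Path(path)
    per_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6, got {len(parts)} columns")
            chrom, start, end, _name, _score, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand == "+":
                per_key[(chrom, W)].append(s)
            elif strand == "-":
                per_key[(chrom, C)].append(e - 1)
            else:
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
    ds = TagDataset(sample=sample or path.stem)
    for (chrom, strand), coords in per_key.items():
        ds.add_tags(chrom, strand, coords)
    return ds


def write_tags_bed(tags: TagDataset, path: str | Path) -> None:
    """One BED6 record per tag (1-bp feature at the 5' end, score=1)."""
    with open(path, "w") as fh:
        for (chrom, strand), arr in tags.items():
            sym = "+" if strand == W else "-"
            for i, pos in enumerate(arr):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttag{i}\t1\t{sym}\n")


def tags_from_alignments(path: str | Path, sample: str | None = None) -> TagDataset:
    """Extract 5'-end tags from SAM/BAM; unmapped and secondary records skipped."""
    import pysam

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ds = TagDataset(sample=sample or path.stem)
    per_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    n_mapped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            n_mapped += 1
            if rec.is_reverse:
                per_key[(rec.reference_name, C)].append(rec.reference_end - 1)
            else:
                per_key[(rec.reference_name, W)].append(rec.reference_start)
    if n_mapped == 0:
        warnings.warn(f"{path}: no mapped reads; returning empty dataset", stacklevel=2)
    for (chrom, strand), coords in per_key.items():
        ds.add_tags(chrom, strand, coords)
    return ds


def read_tss_table(path: str | Path) -> dict[str, TssRecord]:
    """Read a TSS table (TSV: gene_id, chrom, strand, tss). Duplicate gene ids
    accumulate TSS coordinates under one record."""
    records: dict[str, TssRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns (gene, chrom, strand, tss)")
            gene, chrom, strand, tss = parts[0], parts[1], parts[2], int(parts[3])
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            rec = records.get(gene)
            if rec is None:
                records[gene] = TssRecord(gene, chrom, strand, [tss])
            else:
                if rec.chrom != chrom or rec.strand != strand:
                    raise ValueError(f"{path}:{lineno}: gene {gene} spans chrom/strand")
                rec.positions.append(tss)
    return records


def write_tss_table(records: Mapping[str, TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(records):
            rec = records[gene]
            for tss in rec.positions:
                fh.write(f"{rec.gene_id}\t{rec.chrom}\t{rec.strand}\t{tss}\n")


def read_intervals_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    """BED intervals into an IntervalSet. The label is the BED name column if
    present, else the supplied default."""
    ivs = IntervalSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            name = parts[3] if len(parts) >= 4 and parts[3] != "." else (label or "")
            ivs.add(parts[0], int(parts[1]), int(parts[2]), name)
    return ivs


def write_intervals_bed(ivs: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, lab in ivs:
            fh.write(f"{chrom}\t{start}\t{end}\t{lab or '.'}\t0\t+\n")


def write_peak_pairs(pairs, path: str | Path) -> None:
    """TSV: chrom, W summit, C summit, midpoint, span, occupancy, sample."""
    with open(path, "w") as fh:
        fh.write("chrom\tw_summit\tc_summit\tmidpoint\tspan\toccupancy\tsample\n")
        for p in pairs:
            fh.write(f"{p.chrom}\t{p.w_summit}\t{p.c_summit}\t{p.midpoint}\t"
                     f"{p.span}\t{p.occupancy}\t{p.sample}\n")


def read_peak_pairs(path: str | Path):
    from .peak_pairing import PeakPair

    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: missing peak-pair header")
        for line in fh:
            chrom, w, c, _mid, _span, occ, sample = line.rstrip("\n").split("\t")
            out.append(PeakPair(chrom=chrom, w_summit=int(w), c_summit=int(c),
                                occupancy=int(occ), sample=sample))
    return out
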