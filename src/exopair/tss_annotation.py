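"""Assignment of bound locations to TSSs, CpG islands and genome segments.

A peak-pair location is assigned to the nearest annotated TSS within
``max_dist`` bp (absolute midpoint-to-TSS distance, default 500). For genes
with several annotated TSSs the nearest one is the primary TSS; the rest are
secondary. The signed offset is strand-oriented: negative means upstream of
the TSS in the gene's direction of transcription, so e.g. a general factor
sitting over the TATA region of a minus-strand gene still reports a negative
offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .genome_io import IntervalSet, TssRecord
from .peak_pairing import PeakPair


@dataclass(frozen=True)
class TssAssignment:
    pair: PeakPair
    gene_id: str
    tss: int            # coordinate of the primary TSS for this pair
    offset: int         # strand-oriented signed midpoint - TSS distance
    strand: str


@dataclass
class AssignmentResult:
    assigned: list[TssAssignment]
    distal: list[PeakPair]

    def genes(self) -> set[str]:
        """Nonredundant detected gene set."""
        return {a.gene_id for a in self.assigned}


def _flat_tss(tss_set: Mapping[str, TssRecord]):
    """Per-chrom sorted arrays of (tss, gene, strand) for nearest-TSS lookup."""
    per_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for rec in tss_set.values():
        for pos in rec.positions:
            per_chrom.setdefault(rec.chrom, []).append((pos, rec.gene_id, rec.strand))
    out = {}
    for chrom, entries in per_chrom.items():
        entries.sort()
        out[chrom] = (np.asarray([e[0] for e in entries]), entries)
    return out


def assign_to_tss(pairs: Iterable[PeakPair], tss_set: Mapping[str, TssRecord],
                  max_dist: int = 500) -> AssignmentResult:
    """Assign each pair to its nearest TSS within ``max_dist``; ties broken to
    the smaller TSS coordinate. Pairs with no TSS in range are TSS-distal."""
    flat = _flat_tss(tss_set)
    assigned: list[TssAssignment] = []
    distal: list[PeakPair] = []
    for pair in pairs:
        chrom_data = flat.get(pair.chrom)
        if chrom_data is None:
            distal.append(pair)
            continue
        coords, entries = chrom_data
        mid = pair.midpoint
        i = int(np.searchsorted(coords, mid))
        best = None  # (abs distance, tss coordinate, entry index)
        for k in (i - 1, i):
            if 0 <= k < coords.size:
                d = abs(int(coords[k]) - mid)
                cand = (d, int(coords[k]), k)
                if best is None or cand < best:
                    best = cand
        # ties between equidistant TSSs resolve to the smaller coordinate
        # because (distance, coordinate) sorts lexicographically
        if best is None or best[0] > max_dist:
            distal.append(pair)
            continue
        tss, gene, strand = entries[best[2]]
        raw = mid - tss
        offset = raw if strand == "+" else -raw
        assigned.append(TssAssignment(pair, gene, tss, offset, strand))
    return AssignmentResult(assigned=assigned, distal=distal)


def detection_overlap(sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Full Venn decomposition of 2-3 gene-id sets.

    Region keys name the member sets joined by ``&`` for inclusion and
    prefixed ``only:``/listed combinations, e.g. for sets A,B,C the key
    ``A&B`` counts genes in A and B but not C.
    """
    names = sorted(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("detection_overlap expects 2 or 3 sets")
    universe = set().union(*sets.values())
    counts: dict[str, int] = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for n in combo:
                inside &= sets[n]
            for n in names:
                if n not in combo:
                    inside -= sets[n]
            counts["&".join(combo)] = len(inside)
    counts["union"] = len(universe)
    return counts


@dataclass
class CpgSummary:
    n_islands_occupied: int
    n_locations_in_islands: int
    mean_per_occupied_island: float | None
    fraction_genes_with_island_location: float | None


def mean_locations_per_island(n_locations: int, n_islands: int) -> float:
    """Average bound locations per occupied island from two counts."""
    if n_islands <= 0:
        raise ValueError("need at least one island")
    return n_locations / n_islands


def cpg_overlap(pairs: Iterable[PeakPair], islands: IntervalSet,
                assignments: AssignmentResult | None = None) -> CpgSummary:
    """Count bound locations per CpG island (midpoint-in-interval).

    If TSS assignments are supplied, additionally reports the fraction of
    TSS-assigned genes whose island (the island containing the gene's TSS)
    holds at least one location.
    """
    per_island: dict[tuple[str, int, int], int] = {}
    n_in = 0
    for p in pairs:
        hits = islands.query_point(p.chrom, p.midpoint)
        if hits:
            start, end, _ = hits[0]
            per_island[(p.chrom, start, end)] = per_island.get((p.chrom, start, end), 0) + 1
            n_in += 1
    n_occ = len(per_island)
    mean = mean_locations_per_island(n_in, n_occ) if n_occ else None
    frac = None
    if assignments is not None and assignments.assigned:
        genes_with = set()
        all_genes = set()
        for a in assignments.assigned:
            all_genes.add(a.gene_id)
            for start, end, _ in islands.query_point(a.pair.chrom, a.tss):
                if (a.pair.chrom, start, end) in per_island:
                    genes_with.add(a.gene_id)
                    break
        frac = len(genes_with) / len(all_genes)
    return CpgSummary(n_occ, n_in, mean, frac)


def classify_segments(pairs: Iterable[PeakPair],
                      segments: IntervalSet | None) -> tuple[dict[str, float], int]:
    """Fraction of locations per segment class (first interval by file order
    wins on overlap); returns (fractions over classified, n unclassified)."""
    counts: dict[str, int] = {}
    unclassified = 0
    for p in pairs:
        label = segments.first_label_at(p.chrom, p.midpoint) if segments is not None else None
        if label is None:
            unclassified += 1
        else:
            counts[label] = counts.get(label, 0) + 1
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()} if total else {}
    return fractions, unclassified
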