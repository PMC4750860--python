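"""Cross-sample occupancy matrices, detection grouping, k-means partitioning
and sample-level hierarchical clustering.

The occupancy matrix holds genes as rows and samples (cell lines) as columns;
zero means "not detected", which is kept distinct from low occupancy through
normalization and clustering. Genes detected in every sample form Group 1
(constitutively occupied, housekeeping-like); the remainder is partitioned by
k-means into further groups ordered by descending mean occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.cluster import KMeans

from .tss_annotation import AssignmentResult


@dataclass
class OccupancyMatrix:
    gene_ids: list[str]
    samples: list[str]
    values: np.ndarray          # (n_genes, n_samples), 0 = not detected
    normalized: bool = False
    detected: np.ndarray | None = None  # bool mask of originally nonzero cells

    def __post_init__(self) -> None:
        if self.detected is None:
            self.detected = self.values > 0


def build_matrix(per_sample: Mapping[str, AssignmentResult]) -> OccupancyMatrix:
    """Gene x sample matrix of summed pair occupancy; a gene row exists iff
    the gene is detected in at least one sample."""
    samples = sorted(per_sample)
    totals: dict[str, dict[str, float]] = {}
    for sample in samples:
        for a in per_sample[sample].assigned:
            totals.setdefault(a.gene_id, {}).setdefault(sample, 0.0)
            totals[a.gene_id][sample] += a.pair.occupancy
    genes = sorted(totals)
    values = np.zeros((len(genes), len(samples)))
    for i, g in enumerate(genes):
        for j, s in enumerate(samples):
            values[i, j] = totals[g].get(s, 0.0)
    return OccupancyMatrix(genes, samples, values)


def normalize_columns(matrix: OccupancyMatrix) -> OccupancyMatrix:
    """Per column: log2(v+1) over detected entries, centered on the column
    mean of those entries. Zeros stay zero-valued but remain flagged
    not-detected so displays can render them distinctly."""
    if matrix.normalized:
        raise ValueError("matrix already normalized")
    vals = matrix.values.copy()
    det = matrix.detected
    for j in range(vals.shape[1]):
        col = det[:, j]
        if col.any():
            lv = np.log2(vals[col, j] + 1.0)
            vals[col, j] = lv - lv.mean()
        vals[~col, j] = 0.0
    return OccupancyMatrix(list(matrix.gene_ids), list(matrix.samples), vals,
                           normalized=True, detected=det.copy())


def group_by_detection(matrix: OccupancyMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(group1 row indices, remainder row indices): Group 1 = detected in
    every sample."""
    all_det = matrix.detected.all(axis=1)
    return np.flatnonzero(all_det), np.flatnonzero(~all_det)


def kmeans_groups(matrix: OccupancyMatrix, rows: np.ndarray, k: int = 3,
                  seed: int = 0, restarts: int = 100) -> dict[int, np.ndarray]:
    """k-means on the normalized remainder rows.

    Not-detected cells are imputed at (column minimum over detected entries)
    minus 1 log2 unit, keeping "absent" below any observed occupancy. Labels
    are renumbered 2..k+1 by descending cluster mean; rows within each group
    are sorted by cross-sample mean occupancy (descending).
    """
    if not matrix.normalized:
        raise ValueError("kmeans_groups expects a column-normalized matrix")
    X = matrix.values[rows].copy()
    det = matrix.detected[rows]
    for j in range(X.shape[1]):
        col_det = matrix.detected[:, j]
        floor = matrix.values[col_det, j].min() - 1.0 if col_det.any() else -1.0
        X[~det[:, j], j] = floor
    k_eff = min(k, X.shape[0])
    km = KMeans(n_clusters=k_eff, init="k-means++", n_init=restarts,
                random_state=seed)
    labels = km.fit_predict(X)
    order = np.argsort(-np.array([X[labels == c].mean() for c in range(k_eff)]))
    relabel = {int(c): g + 2 for g, c in enumerate(order)}
    groups: dict[int, np.ndarray] = {}
    for c in range(k_eff):
        g = relabel[c]
        members = rows[labels == c]
        means = X[labels == c].mean(axis=1)
        groups[g] = members[np.argsort(-means, kind="stable")]
    return groups


@dataclass
class SampleDendrogram:
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str


def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_samples(matrix: OccupancyMatrix) -> SampleDendrogram:
    """Average-linkage hierarchical clustering of samples; distance =
    1 - Pearson r over genes detected in both samples of each pair."""
    n = len(matrix.samples)
    if n < 2:
        raise ValueError("need >= 2 samples to cluster")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = matrix.detected[:, i] & matrix.detected[:, j]
            if both.sum() < 3:
                d = 1.0
            else:
                a, b = matrix.values[both, i], matrix.values[both, j]
                if np.std(a) == 0 or np.std(b) == 0:
                    d = 1.0 if not np.array_equal(a, b) else 0.0
                else:
                    d = 1.0 - pearsonr(a, b)[0]
            D[i, j] = D[j, i] = max(d, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    tree = hierarchy.to_tree(Z)
    leaves = hierarchy.leaves_list(Z)
    newick = _newick(tree, matrix.samples) + ";"
    return SampleDendrogram(Z, [matrix.samples[i] for i in leaves], newick)
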