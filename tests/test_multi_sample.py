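"""Occupancy matrix construction, grouping, k-means and sample clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from exopair.genome_io import TssRecord
from exopair.multi_sample import (OccupancyMatrix, build_matrix, cluster_samples,
                                  group_by_detection, kmeans_groups,
                                  normalize_columns)
from exopair.peak_pairing import PeakPair
from exopair.tss_annotation import assign_to_tss


def _assignments(gene_pairs):
    """gene_pairs: {gene: [(midpoint, occupancy), ...]} on one + strand TSS per gene."""
    tss = {g: TssRecord(g, "chr1", "+", [10_000 * (i + 1)])
           for i, g in enumerate(sorted(gene_pairs))}
    pairs = []
    for g, plist in gene_pairs.items():
        base = tss[g].positions[0]
        for off, occ in plist:
            mid = base + off
            pairs.append(PeakPair("chr1", mid - 10, mid + 10, occ))
    return assign_to_tss(pairs, tss)


class TestBuildMatrix:
    def test_gene_detected_in_one_sample_has_one_nonzero(self):
        mat = build_matrix({
            "s1": _assignments({"g1": [(-20, 5)]}),
            "s2": _assignments({}),
        })
        assert mat.gene_ids == ["g1"]
        assert mat.values.tolist() == [[5.0, 0.0]]

    def test_no_detections_anywhere_gives_empty_matrix(self):
        mat = build_matrix({"s1": _assignments({}), "s2": _assignments({})})
        assert mat.values.shape == (0, 2)

    def test_multiple_pairs_per_gene_sum(self):
        mat = build_matrix({"s1": _assignments({"g1": [(-20, 5), (30, 7)]})})
        assert mat.values.tolist() == [[12.0]]


class TestNormalizeColumns:
    def test_identical_nonzero_column_centers_to_zero(self):
        mat = OccupancyMatrix(["a", "b"], ["s"], np.array([[7.0], [7.0]]))
        assert normalize_columns(mat).values.tolist() == [[0.0], [0.0]]

    def test_zeros_stay_flagged_not_detected(self):
        mat = OccupancyMatrix(["a", "b"], ["s"], np.array([[8.0], [0.0]]))
        norm = normalize_columns(mat)
        assert not norm.detected[1, 0]
        assert norm.values[1, 0] == 0.0

    def test_column_scaling_is_removed_by_centering(self, rng):
        v = rng.random((10, 1)) * 50 + 1
        a = normalize_columns(OccupancyMatrix(list("abcdefghij"), ["s"], v.copy()))
        b = normalize_columns(OccupancyMatrix(list("abcdefghij"), ["s"], 2 * v + 1))
        # doubling shifts log2 values by ~1; centering removes the shift so
        # the relative pattern is preserved
        assert np.corrcoef(a.values[:, 0], b.values[:, 0])[0, 1] > 0.999


class TestDetectionGrouping:
    def test_partition_into_group1_and_remainder(self):
        vals = np.array([[5, 3, 7, 2], [5, 0, 7, 2], [1, 1, 1, 1]], dtype=float)
        mat = OccupancyMatrix(list("abc"), list("wxyz"), vals)
        g1, rest = group_by_detection(mat)
        assert mat.gene_ids[g1[0]] == "a" and len(g1) == 2
        assert [mat.gene_ids[i] for i in rest] == ["b"]

    def test_groups_partition_all_rows(self, rng):
        vals = rng.integers(0, 5, (30, 4)).astype(float)
        vals[vals.sum(axis=1) == 0, 0] = 1  # build_matrix invariant
        mat = OccupancyMatrix([f"g{i}" for i in range(30)], list("wxyz"), vals)
        norm = normalize_columns(mat)
        g1, rest = group_by_detection(norm)
        groups = kmeans_groups(norm, rest, k=3, seed=0, restarts=10) if rest.size else {}
        all_rows = sorted(g1.tolist() + [i for m in groups.values() for i in m.tolist()])
        assert all_rows == list(range(30))


class TestKmeans:
    def _planted(self, rng, centers, n_per=20):
        rows, labels = [], []
        for ci, c in enumerate(centers):
            for _ in range(n_per):
                rows.append(np.array(c) + rng.normal(0, 0.05, len(c)))
                labels.append(ci)
        vals = 2.0 ** np.array(rows)  # back to occupancy scale, all detected
        genes = [f"g{i}" for i in range(len(rows))]
        mat = OccupancyMatrix(genes, [f"s{j}" for j in range(len(centers[0]))], vals)
        return normalize_columns(mat), np.array(labels)

    def test_well_separated_clusters_recovered_exactly(self, rng):
        norm, truth = self._planted(rng, [(8, 8, 1, 1), (1, 8, 8, 1), (1, 1, 1, 8)])
        rows = np.arange(len(truth))
        groups = kmeans_groups(norm, rows, k=3, seed=0, restarts=20)
        pred = np.empty(len(truth), dtype=int)
        for g, members in groups.items():
            pred[members] = g
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_k_equal_n_puts_each_row_alone(self, rng):
        norm, _ = self._planted(rng, [(5, 1), (1, 5)], n_per=2)
        groups = kmeans_groups(norm, np.arange(4), k=4, seed=0, restarts=5)
        assert sorted(len(m) for m in groups.values()) == [1, 1, 1, 1]

    def test_fixed_seed_is_deterministic(self, rng):
        norm, truth = self._planted(rng, [(6, 1, 1), (1, 6, 1), (1, 1, 6)])
        rows = np.arange(len(truth))
        a = kmeans_groups(norm, rows, k=3, seed=7, restarts=10)
        b = kmeans_groups(norm, rows, k=3, seed=7, restarts=10)
        assert {g: m.tolist() for g, m in a.items()} == \
               {g: m.tolist() for g, m in b.items()}

    def test_group_labels_ordered_by_descending_mean_occupancy(self, rng):
        norm, _ = self._planted(rng, [(8, 8, 8), (4, 4, 4), (1, 1, 1)])
        groups = kmeans_groups(norm, np.arange(60), k=3, seed=0, restarts=10)
        means = {g: norm.values[m].mean() for g, m in groups.items()}
        assert means[2] > means[3] > means[4]


class TestClusterSamples:
    def test_identical_columns_merge_at_height_zero(self, rng):
        col = rng.random(20) * 9 + 1
        vals = np.column_stack([col, col, rng.random(20) * 9 + 1])
        mat = normalize_columns(OccupancyMatrix([f"g{i}" for i in range(20)],
                                                ["a", "b", "c"], vals))
        dend = cluster_samples(mat)
        assert dend.linkage[0, 2] == pytest.approx(0.0, abs=1e-9)
        assert set(dend.leaf_order) == {"a", "b", "c"}

    def test_planted_similarity_makes_sisters(self, rng):
        base = rng.normal(5, 1, 40)
        a = base + rng.normal(0, 0.1, 40)
        b = base + rng.normal(0, 0.1, 40)
        c = rng.normal(5, 1, 40)
        vals = 2.0 ** np.column_stack([a, b, c])
        mat = normalize_columns(OccupancyMatrix([f"g{i}" for i in range(40)],
                                                ["A", "B", "C"], vals))
        dend = cluster_samples(mat)
        # first merge joins the two correlated samples
        i, j = int(dend.linkage[0, 0]), int(dend.linkage[0, 1])
        assert {mat.samples[i], mat.samples[j]} == {"A", "B"}
        assert dend.newick.count("(") == 2 and dend.newick.endswith(";")

    def test_two_samples_give_single_join(self, rng):
        vals = rng.random((10, 2)) * 9 + 1
        mat = normalize_columns(OccupancyMatrix([f"g{i}" for i in range(10)],
                                                ["x", "y"], vals))
        dend = cluster_samples(mat)
        assert dend.linkage.shape == (1, 4)

    def test_single_sample_rejected(self):
        mat = OccupancyMatrix(["g"], ["only"], np.array([[1.0]]))
        with pytest.raises(ValueError):
            cluster_samples(mat)
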