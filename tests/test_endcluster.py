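"""Feature-table normalization and Ward.D2 agglomeration."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from telomir import endcluster as ec


class TestBuildEndTable:
    def test_columns_normalized_to_mean_one(self):
        raw = pd.DataFrame({"we_count": [2.0, 4.0, 6.0]}, index=["a", "b", "c"])
        table, _ = ec.build_end_table(raw)
        assert list(table["we_count"]) == [0.5, 1.0, 1.5]
        assert table["we_count"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_timing_affine_map_to_unit_interval(self):
        raw = pd.DataFrame({"replication_timing": [10.0, 20.0, 30.0]})
        table, _ = ec.build_end_table(raw)
        assert list(table["replication_timing"]) == [-1.0, 0.0, 1.0]

    def test_deg_ratio_from_gene_density(self):
        raw = pd.DataFrame({"deg_count": [5.0, 0.0]}, index=["e1", "e2"])
        genes = pd.Series([50.0, 20.0], index=["e1", "e2"])
        table, meta = ec.build_end_table(raw, gene_counts=genes)
        ratio_mean = (0.1 + 0.0) / 2
        assert table.loc["e1", "deg_ratio"] == pytest.approx(0.1 / ratio_mean)

    def test_zero_gene_end_flagged_not_divided(self):
        raw = pd.DataFrame({"deg_count": [2.0, 1.0]}, index=["e1", "e2"])
        genes = pd.Series([10.0, 0.0], index=["e1", "e2"])
        table, meta = ec.build_end_table(raw, gene_counts=genes)
        assert "deg_ratio_zero_gene_ends" in meta["flags"]
        assert np.isfinite(table["deg_ratio"]).all()

    def test_zero_mean_column_dropped_with_warning(self):
        raw = pd.DataFrame({"a": [1.0, 3.0], "b": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="mean 0"):
            table, meta = ec.build_end_table(raw)
        assert "b" not in table.columns and meta["dropped"] == ["b"]

    def test_missing_values_are_an_error(self):
        raw = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            ec.build_end_table(raw)

    def test_normalization_is_idempotent(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(
            rng.uniform(1, 5, (6, 3)), columns=["x", "y", "replication_timing"]
        )
        once, _ = ec.build_end_table(raw)
        twice, _ = ec.build_end_table(once)
        pd.testing.assert_frame_equal(once, twice, atol=1e-9, rtol=0)


def ward_oracle_euclidean(X: np.ndarray):
    """Greedy Ward agglomeration computed from cluster contents.

    Merge cost between clusters is sqrt(2|A||B|/(|A|+|B|)) * ||cA - cB||,
    evaluated directly from the points at every step (no Lance-Williams
    update), ties to the lexicographically smallest cluster-id pair.
    """
    clusters = {i: [i] for i in range(len(X))}
    heights = []
    merges = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i:
                    continue
                a, b = clusters[i], clusters[j]
                ca, cb = X[a].mean(axis=0), X[b].mean(axis=0)
                cost = np.sqrt(
                    2 * len(a) * len(b) / (len(a) + len(b))
                ) * np.linalg.norm(ca - cb)
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, i, j)
        cost, i, j = best
        heights.append(cost)
        merges.append((i, j))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges, heights


class TestWardD2:
    def test_three_points_on_a_line(self):
        D = ec.manhattan_distances(np.array([[0.0], [1.0], [10.0]]))
        Z = ec.ward_d2_linkage(D)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)

    def test_duplicate_rows_merge_first_at_height_zero(self):
        X = np.array([[1.0, 1.0], [5.0, 5.0], [1.0, 1.0]])
        Z = ec.ward_d2_linkage(ec.manhattan_distances(X))
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 2}
        assert Z[0, 2] == 0.0

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 4))
        Z = ec.ward_d2_linkage(ec.manhattan_distances(X))
        assert (np.diff(Z[:, 2]) >= -1e-9).all()

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_brute_force_ward_criterion(self, n):
        rng = np.random.default_rng(n)
        X = rng.normal(size=(n, 3))
        D = squareform(pdist(X))  # Euclidean
        Z = ec.ward_d2_linkage(D)
        _, oracle_heights = ward_oracle_euclidean(X)
        np.testing.assert_allclose(Z[:, 2], oracle_heights, rtol=1e-8)

    def test_matches_scipy_ward_on_euclidean_data(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(15, 5))
        Z_mine = ec.ward_d2_linkage(squareform(pdist(X)))
        Z_scipy = hierarchy.linkage(X, method="ward")
        np.testing.assert_allclose(
            np.sort(Z_mine[:, 2]), np.sort(Z_scipy[:, 2]), rtol=1e-8
        )
        c_mine = squareform(hierarchy.cophenet(Z_mine))
        c_scipy = squareform(hierarchy.cophenet(Z_scipy))
        np.testing.assert_allclose(c_mine, c_scipy, rtol=1e-8)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 3))
        perm = rng.permutation(10)
        Z1 = ec.ward_d2_linkage(ec.manhattan_distances(X))
        Z2 = ec.ward_d2_linkage(ec.manhattan_distances(X[perm]))
        c1 = squareform(hierarchy.cophenet(Z1))
        c2 = squareform(hierarchy.cophenet(Z2))
        np.testing.assert_allclose(c1[np.ix_(perm, perm)], c2, rtol=1e-9)

    def test_matches_r_hclust_ward_d2_manhattan(self, tmp_path):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(9, 4))
        D = ec.manhattan_distances(X)
        Z = ec.ward_d2_linkage(D)
        dpath = tmp_path / "d.tsv"
        np.savetxt(dpath, D, delimiter="\t")
        script = (
            f"d <- as.dist(as.matrix(read.table('{dpath}')));"
            "h <- hclust(d, method='ward.D2');"
            "cat(sort(h$height), sep='\\n')"
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_heights = np.array([float(x) for x in res.stdout.split()])
        np.testing.assert_allclose(np.sort(Z[:, 2]), r_heights, rtol=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ec.ward_d2_linkage(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            ec.cluster_ends(pd.DataFrame({"a": [1.0, 2.0]}), k=5)


class TestClusterEnds:
    def test_planted_two_group_structure_recovered(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 0.1, size=(6, 3))
        b = rng.normal(5, 0.1, size=(5, 3))
        table = pd.DataFrame(
            np.vstack([a, b]), index=[f"e{i}" for i in range(11)]
        )
        _, labels = ec.cluster_ends(table, k=2)
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_newick_serialization_has_all_leaves(self):
        rng = np.random.default_rng(14)
        table = pd.DataFrame(rng.normal(size=(5, 2)), index=list("abcde"))
        Z, _ = ec.cluster_ends(table, k=2)
        nwk = ec.linkage_to_newick(Z, list(table.index))
        assert nwk.endswith(";")
        for leaf in "abcde":
            assert leaf in nwk
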