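import itertools

import numpy as np
import pandas as pd
import pytest

from htfc.profiling import (
    ClusterTree,
    cut_tree,
    export_dendrogram,
    hcluster,
    knn_impute,
    mean_center,
    pca,
    pearson_distance,
    to_newick,
)


def brute_force_knn_impute(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Exhaustive-search oracle: nan-Euclidean distances and donor means,
    written out longhand."""
    v = matrix.to_numpy(dtype=float)
    n, m = v.shape
    out = v.copy()
    for i in range(n):
        for j in range(m):
            if not np.isnan(v[i, j]):
                continue
            dists = []
            for r in range(n):
                if r == i or np.isnan(v[r, j]):
                    continue
                both = ~np.isnan(v[i]) & ~np.isnan(v[r])
                diff2 = ((v[i, both] - v[r, both]) ** 2).sum()
                dists.append((np.sqrt(m / both.sum() * diff2), r))
            dists.sort(key=lambda t: t[0])
            donors = [r for _, r in dists[:k]]
            out[i, j] = np.mean([v[r, j] for r in donors])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def naive_complete_linkage(d: np.ndarray):
    """O(n^3) agglomeration oracle returning sorted merge heights."""
    clusters = {i: [i] for i in range(len(d))}
    heights = []
    next_id = len(d)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


class TestKnnImpute:
    def test_complete_matrix_unchanged(self):
        m = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        pd.testing.assert_frame_equal(knn_impute(m, 2), m)

    def test_k1_copies_identical_neighbor(self):
        m = pd.DataFrame(
            [[1.0, 2.0, np.nan], [1.0, 2.0, 7.0], [50.0, 60.0, 70.0]],
            columns=["a", "b", "c"],
        )
        out = knn_impute(m, 1)
        assert out.iloc[0, 2] == 7.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.uniform(0, 100, (6, 4)), columns=list("abcd"))
        m.iloc[0, 1] = np.nan
        m.iloc[3, 2] = np.nan
        out = knn_impute(m, 2)
        oracle = brute_force_knn_impute(m, 2)
        pd.testing.assert_frame_equal(out, oracle)

    def test_imputed_values_within_observed_column_range(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.uniform(0, 100, (12, 6)))
        mask = rng.random((12, 6)) < 0.2
        mask[:, 0] &= rng.random(12) < 0.5  # keep every column partly observed
        mv = m.where(~mask)
        mv = mv.dropna(how="all")
        out = knn_impute(mv, 3)
        for c in mv.columns:
            observed = mv[c].dropna()
            assert out[c].min() >= observed.min() - 1e-12
            assert out[c].max() <= observed.max() + 1e-12

    def test_k_truncated_to_available_donors(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 5.0], [3.0, 9.0]])
        out = knn_impute(m, 10)
        assert out.iloc[0, 1] == pytest.approx(7.0)

    def test_fully_missing_column_errors_with_name(self):
        m = pd.DataFrame({"ok": [1.0, 2.0], "gone": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="gone"):
            knn_impute(m, 1)


class TestMeanCenter:
    def test_column_example(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert list(mean_center(m)["a"]) == [-1.0, 0.0, 1.0]

    def test_idempotent_and_zero_mean(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.uniform(0, 100, (7, 5)))
        c1 = mean_center(m)
        c2 = mean_center(c1)
        pd.testing.assert_frame_equal(c1, c2)
        assert (c1.mean(axis=0).abs() < 1e-12).all()


class TestPearsonDistance:
    def test_self_distance_zero(self):
        m = pd.DataFrame([[1.0, 5.0, 2.0], [1.0, 5.0, 2.0]], index=["x", "y"])
        d = pearson_distance(m)
        assert d.loc["x", "y"] == pytest.approx(0.0)

    def test_anticorrelation_is_two(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        m = pd.DataFrame([x, -x + 3], index=["x", "y"])
        assert pearson_distance(m).loc["x", "y"] == pytest.approx(2.0)

    def test_three_sample_covariance_formula(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 4.0], [2.0, 1.0, 3.0], [8.0, 2.0, 5.0]], index=list("abc")
        )
        v = m.to_numpy()

        def rho(x, y):
            xc, yc = x - x.mean(), y - y.mean()
            return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())

        d = pearson_distance(m)
        for i, j in itertools.combinations(range(3), 2):
            assert d.iloc[i, j] == pytest.approx(1 - rho(v[i], v[j]), abs=1e-12)

    def test_range_bounded(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(10, 8)))
        d = pearson_distance(m).to_numpy()
        assert d.min() >= 0.0 and d.max() <= 2.0

    def test_constant_row_errors_with_name(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            pearson_distance(m)


class TestHCluster:
    def test_two_samples_single_merge(self):
        d = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]], index=["a", "b"], columns=["a", "b"])
        tree = hcluster(d)
        assert tree.linkage.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(0.7)

    def test_merge_heights_match_naive_agglomeration(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(5, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = pd.DataFrame(d, index=list("abcde"), columns=list("abcde"))
        tree = hcluster(dm)
        np.testing.assert_allclose(
            np.sort(tree.heights), naive_complete_linkage(d), rtol=1e-12
        )

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.uniform(0, 100, (9, 6)))
        tree = hcluster(pearson_distance(m))
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_planted_two_groups_recovered(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 0.05, (4, 6)) + np.array([1, 2, 3, 4, 5, 6.0])
        b = rng.normal(0, 0.05, (4, 6)) + np.array([6, 5, 4, 3, 2, 1.0])
        m = pd.DataFrame(np.vstack([a, b]), index=[f"s{i}" for i in range(8)])
        labels = cut_tree(hcluster(pearson_distance(m)), 2)
        assert labels[:4].nunique() == 1 and labels[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_row_permutation_invariance_up_to_relabel(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(rng.uniform(0, 100, (8, 5)), index=[f"s{i}" for i in range(8)])
        perm = rng.permutation(8)
        t1 = cut_tree(hcluster(pearson_distance(m)), 3)
        t2 = cut_tree(hcluster(pearson_distance(m.iloc[perm])), 3)
        # same partition of sample names
        p1 = {frozenset(t1.index[t1 == c]) for c in t1.unique()}
        p2 = {frozenset(t2.index[t2 == c]) for c in t2.unique()}
        assert p1 == p2

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            hcluster(d)


class TestCutTree:
    @pytest.fixture()
    def tree(self):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(rng.uniform(0, 100, (6, 4)), index=[f"s{i}" for i in range(6)])
        return hcluster(pearson_distance(m))

    def test_k_equals_n(self, tree):
        labels = cut_tree(tree, 6)
        assert labels.nunique() == 6

    def test_k_equals_one(self, tree):
        assert cut_tree(tree, 1).nunique() == 1

    def test_labels_ordered_by_first_appearance(self, tree):
        labels = cut_tree(tree, 3)
        seen = []
        for v in labels:
            if v not in seen:
                seen.append(v)
        assert seen == sorted(seen)

    def test_k_out_of_range(self, tree):
        with pytest.raises(ValueError):
            cut_tree(tree, 7)


class TestPCA:
    def test_collinear_data_single_component(self):
        t = np.linspace(0, 1, 8)
        m = pd.DataFrame({"a": 2 * t, "b": -3 * t, "c": 5 * t})
        r = pca(m)
        assert r.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_data_near_equal_variances(self):
        rng = np.random.default_rng(15)
        m = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["x", "y"])
        r = pca(m)
        assert r.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(16)
        m = pd.DataFrame(rng.uniform(0, 10, (5, 3)), columns=list("abc"))
        x = m.to_numpy() - m.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(x.T @ x)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        r = pca(m)
        np.testing.assert_allclose(
            r.explained_variance_ratio, evals / evals.sum(), atol=1e-10
        )
        for c in range(3):
            v = evecs[:, c]
            np.testing.assert_allclose(
                np.abs(r.loadings.iloc[:, c]), np.abs(v), atol=1e-8
            )
        # scores reproduce the centered data
        np.testing.assert_allclose(
            r.scores.to_numpy() @ r.loadings.to_numpy().T, x, atol=1e-8
        )

    def test_sign_convention(self):
        rng = np.random.default_rng(17)
        m = pd.DataFrame(rng.uniform(0, 10, (6, 4)))
        r = pca(m)
        for c in r.loadings.columns:
            col = r.loadings[c]
            assert col.iloc[col.abs().to_numpy().argmax()] > 0

    def test_overrequested_components_truncate_with_warning(self):
        t = np.linspace(0, 1, 5)
        m = pd.DataFrame({"a": t, "b": 2 * t})
        with pytest.warns(UserWarning, match="rank"):
            r = pca(m, n_components=2)
        assert r.loadings.shape[1] == 1


class TestDendrogramExport:
    def test_two_leaf_convention(self):
        d = pd.DataFrame([[0.0, 0.8], [0.8, 0.0]], index=["A", "B"], columns=["A", "B"])
        assert to_newick(hcluster(d)) == "(A:0.4,B:0.4);"

    def test_round_trip_preserves_leaves_and_heights(self, tmp_path):
        import io

        from Bio import Phylo

        rng = np.random.default_rng(18)
        m = pd.DataFrame(rng.uniform(0, 100, (6, 5)), index=[f"s{i}" for i in range(6)])
        tree = hcluster(pearson_distance(m))
        nwk = to_newick(tree)
        parsed = Phylo.read(io.StringIO(nwk), "newick")
        leaves = {t.name for t in parsed.get_terminals()}
        assert leaves == set(tree.labels)
        # ultrametric: every leaf sits at half the root merge height
        root_h = tree.heights[-1] / 2
        for t in parsed.get_terminals():
            assert parsed.distance(t) == pytest.approx(root_h, rel=1e-6)

    def test_export_writes_tree_and_leaf_order(self, tmp_path):
        d = pd.DataFrame([[0.0, 0.8], [0.8, 0.0]], index=["A", "B"], columns=["A", "B"])
        tree = hcluster(d)
        out = tmp_path / "tree.nwk"
        export_dendrogram(tree, out)
        assert out.read_text().startswith("(")
        order = pd.read_csv(tmp_path / "tree.order.csv")
        assert set(order["leaf"]) == {"A", "B"}
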