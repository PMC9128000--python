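import numpy as np
import pandas as pd
import pytest

from foragedecomp.discovery import (assign_modules, cluster_ward,
                                    compute_centroids, cut_tree_hybrid,
                                    greedy_decorrelate, igp,
                                    igp_permutation_test, ModuleSet,
                                    null_cluster_count_test,
                                    partition_balanced, sweep_thresholds)
from foragedecomp.experiments import _igp_brute_force
from foragedecomp.fdr import estimate_pi0, qvalues


def _corr(names, entries):
    """Symmetric correlation DataFrame from {(i, j): r}."""
    k = len(names)
    c = np.eye(k)
    for (i, j), r in entries.items():
        c[i, j] = c[j, i] = r
    return pd.DataFrame(c, index=names, columns=names)


class TestGreedyDecorrelate:
    def test_identity_matrix_keeps_all(self):
        corr = _corr(list("abcd"), {})
        assert greedy_decorrelate(corr, 0.8) == list("abcd")

    def test_drops_member_with_larger_mean_correlation(self):
        # |r(a,b)|=0.9 > cutoff; mean|r|: a = 0.6, b = 0.5 -> drop a
        corr = _corr(list("abc"), {(0, 1): 0.9, (0, 2): 0.3, (1, 2): 0.1})
        assert greedy_decorrelate(corr, 0.8) == ["b", "c"]

    def test_fully_correlated_block_leaves_one(self):
        corr = _corr(list("abcd"), {(i, j): 0.95 for i in range(4)
                                    for j in range(i + 1, 4)})
        assert len(greedy_decorrelate(corr, 0.8)) == 1

    def test_matches_exhaustive_oracle_on_small_instances(self):
        """Final retained set never contains a pair above the cutoff, and is
        maximal: no removed measure could be added back."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            k = int(rng.integers(3, 7))
            X = rng.normal(size=(40, k))
            X[:, -1] = X[:, 0] + rng.normal(0, 0.1, size=40)
            corr = pd.DataFrame(np.corrcoef(X, rowvar=False),
                                index=range(k), columns=range(k))
            cutoff = float(rng.uniform(0.3, 0.9))
            kept = greedy_decorrelate(corr, cutoff)
            sub = corr.loc[kept, kept].to_numpy()
            np.fill_diagonal(sub, 0.0)
            assert np.abs(sub).max() <= cutoff + 1e-12

    def test_asymmetric_rejected(self):
        c = _corr(list("ab"), {(0, 1): 0.5})
        c.iloc[0, 1] = 0.4
        with pytest.raises(ValueError):
            greedy_decorrelate(c, 0.8)


class TestWardClustering:
    def test_two_points_merge_at_their_distance(self):
        Z = cluster_ward(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert Z[0, 2] == pytest.approx(5.0)

    def test_collinear_first_merge_is_closest_pair(self):
        Z = cluster_ward(np.array([[0.0], [1.0], [10.0]]))
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_merge_heights_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        h1 = np.sort(cluster_ward(X)[:, 2])
        h2 = np.sort(cluster_ward(X[rng.permutation(30)])[:, 2])
        np.testing.assert_allclose(h1, h2, rtol=1e-9)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_ward(np.array([[1.0, 2.0]]))


class TestHybridCut:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (50, 8)),
                       rng.normal(0, 1, (50, 8)) + 8 / np.sqrt(8)])
        labels = cut_tree_hybrid(cluster_ward(X), deep_split=1,
                                 min_cluster_size=20)
        assert labels.max() == 2
        truth = np.repeat([1, 2], 50)
        purity = max((labels == truth).mean(), (labels == 3 - truth).mean())
        assert purity >= 0.95

    def test_min_cluster_size_above_n_unassigns_all(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        labels = cut_tree_hybrid(cluster_ward(X), min_cluster_size=31)
        assert (labels == 0).all()

    def test_single_tight_blob_stays_whole_at_deep_split_0(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            X = rng.normal(size=(100, 8))
            labels = cut_tree_hybrid(cluster_ward(X), deep_split=0,
                                     min_cluster_size=20)
            assert labels.max() == 1

    def test_six_planted_clusters_at_study_parameters(self):
        rng = np.random.default_rng(3)
        centers = rng.normal(0, 8, (6, 12))
        X = np.vstack([rng.normal(0, 1, (30, 12)) + c for c in centers])
        labels = cut_tree_hybrid(cluster_ward(X), deep_split=4,
                                 min_cluster_size=20)
        assert labels.max() == 6

    def test_no_cluster_below_min_size(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 6))
        labels = cut_tree_hybrid(cluster_ward(X), deep_split=4,
                                 min_cluster_size=20)
        for k in range(1, labels.max() + 1):
            assert (labels == k).sum() >= 20

    def test_invalid_deep_split_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            cut_tree_hybrid(cluster_ward(rng.normal(size=(30, 3))),
                            deep_split=7)


class TestSweep:
    def test_duplicate_columns_pruned_without_losing_clusters(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(0, 8, (3, 6))
        X = np.vstack([rng.normal(0, 1, (40, 6)) + c for c in centers])
        df = pd.DataFrame(X, columns=[f"m{i}" for i in range(6)])
        doubled = pd.concat(
            [df, df.add_suffix("_copy") + rng.normal(0, 1e-6, X.shape)], axis=1)
        s1 = sweep_thresholds(df, grid=[0.9], min_cluster_size=20)
        s2 = sweep_thresholds(doubled, grid=[0.9], min_cluster_size=20)
        assert s1.entries[0][2] == s2.entries[0][2]

    def test_single_value_grid(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(50, 5)))
        s = sweep_thresholds(df, grid=[0.7])
        assert len(s.entries) == 1
        assert s.selected_threshold == 0.7

    def test_tie_prefers_larger_threshold(self):
        rng = np.random.default_rng(2)
        centers = rng.normal(0, 10, (2, 6))
        X = np.vstack([rng.normal(0, 1, (40, 6)) + c for c in centers])
        s = sweep_thresholds(pd.DataFrame(X), grid=[0.6, 0.9])
        counts = {e[0]: e[2] for e in s.entries}
        if counts[0.6] == counts[0.9]:
            assert s.selected_threshold == 0.9

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_thresholds(pd.DataFrame(np.eye(5)), grid=[0.0])


class TestNullClusterCount:
    def test_planted_structure_gives_small_p(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(0, 8, (5, 10))
        X = pd.DataFrame(np.vstack([rng.normal(0, 1, (60, 10)) + c
                                    for c in centers]))
        observed, nulls, p = null_cluster_count_test(X, iterations=200, seed=1)
        assert observed == 5
        assert p <= 0.01

    def test_add_one_formula_with_single_iteration(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(60, 5)))
        *_, p = null_cluster_count_test(X, iterations=1, seed=2)
        assert p in (0.5, 1.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(80, 6)))
        r1 = null_cluster_count_test(X, iterations=50, seed=7)
        r2 = null_cluster_count_test(X, iterations=50, seed=7)
        assert np.array_equal(r1[1], r2[1]) and r1[2] == r2[2]


class TestPartition:
    def _meta(self, n_per=10):
        rows = [{"genotype": g, "sex": s, "phase": "exploration"}
                for g in ("wildtype", "Th het") for s in ("male", "female")
                for _ in range(n_per)]
        return pd.DataFrame(rows)

    def test_half_split_per_stratum(self):
        meta = self._meta(10)
        train, test = partition_balanced(meta, ("genotype", "sex", "phase"),
                                         fraction=0.5, seed=0)
        for _, g in meta.groupby(["genotype", "sex"]):
            assert len(set(train) & set(g.index)) == 5

    def test_round_half_up_on_odd_stratum(self):
        meta = self._meta(3)
        train, test = partition_balanced(meta, ("genotype", "sex", "phase"),
                                         fraction=0.5, seed=0)
        for _, g in meta.groupby(["genotype", "sex"]):
            assert len(set(train) & set(g.index)) == 2  # round(1.5) -> 2

    def test_same_seed_identical(self):
        meta = self._meta(7)
        a = partition_balanced(meta, ("genotype",), seed=11)
        b = partition_balanced(meta, ("genotype",), seed=11)
        assert a == b

    def test_partition_is_disjoint_and_complete(self):
        meta = self._meta(9)
        train, test = partition_balanced(meta, ("genotype", "sex"), seed=3)
        assert set(train) | set(test) == set(meta.index)
        assert not set(train) & set(test)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            partition_balanced(self._meta(2), ("sex",), fraction=1.0)


class TestCentroids:
    def test_mean_of_members(self):
        data = pd.DataFrame([[0.0, 0.0], [2.0, 2.0], [5.0, 5.0]])
        cen = compute_centroids(np.array([1, 1, 2]), data)
        np.testing.assert_allclose(cen.loc[1], [1.0, 1.0])
        np.testing.assert_allclose(cen.loc[2], [5.0, 5.0])

    def test_merged_centroid_is_weighted_mean(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(30, 3)))
        labels = np.array([1] * 10 + [2] * 20)
        cen = compute_centroids(labels, data)
        merged = compute_centroids(np.ones(30, dtype=int), data)
        weighted = (10 * cen.loc[1] + 20 * cen.loc[2]) / 30
        np.testing.assert_allclose(merged.loc[1], weighted, atol=1e-12)

    def test_all_unassigned_rejected(self):
        with pytest.raises(ValueError):
            compute_centroids(np.zeros(5, dtype=int),
                              pd.DataFrame(np.eye(5)))


class TestIgp:
    def test_two_tight_pairs(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        C = np.array([[0.0, 0.0], [10.0, 10.0]])
        np.testing.assert_allclose(igp(X, C), [1.0, 1.0])

    def test_tie_breaks_to_lowest_index(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [10.0, 10.0]])
        C = np.array([[0.0, 0.0], [10.0, 10.0]])
        # (5,5) is centroid-equidistant -> cluster 1; its NN is distance-tied
        # between (0,0) and (10,10) -> lowest index, also cluster 1; the
        # remaining cluster is a singleton and scores 0.
        np.testing.assert_allclose(igp(X, C), [1.0, 0.0])

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0]])
        C = np.array([[0.0, 0.0], [10.0, 0.0]])
        assert igp(X, C)[1] == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            igp(np.zeros((4, 3)), np.zeros((2, 2)))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(5, 101))
            X = rng.normal(size=(n, int(rng.integers(2, 5))))
            C = rng.normal(size=(int(rng.integers(2, 5)), X.shape[1]))
            np.testing.assert_array_equal(igp(X, C), _igp_brute_force(X, C))


class TestIgpPermutation:
    def test_separated_blobs_significant(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.5, (40, 4)),
                       rng.normal(0, 0.5, (40, 4)) + 6])
        C = np.array([[0.0] * 4, [6.0] * 4])
        obs, p = igp_permutation_test(X, C, nperm=200, seed=1)
        assert (obs >= 0.95).all()
        assert (p <= 0.01).all()

    def test_structureless_data_not_enriched(self):
        """Centroids in uniform noise: p-values should not pile up near 0."""
        rng = np.random.default_rng(1)
        small = 0
        n_rep = 40
        for _ in range(n_rep):
            X = rng.uniform(-1, 1, size=(60, 4))
            C = rng.uniform(-1, 1, size=(3, 4))
            _, p = igp_permutation_test(X, C, nperm=99, seed=rng)
            small += int((p < 0.05).any())
        # 3 tests/rep; under calibration P(any p < 0.05) ~ 0.14
        assert small <= 14  # ~ upper binomial bound at rate 0.15

    def test_add_one_formula_bounds(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        C = rng.normal(size=(2, 3))
        _, p = igp_permutation_test(X, C, nperm=1, seed=3)
        assert set(np.round(p, 6)) <= {0.5, 1.0}


class TestQvalues:
    def test_bh_closed_form(self):
        q, _ = qvalues(np.array([0.001, 0.002, 0.9]), pi0=1.0)
        np.testing.assert_allclose(q, [0.003, 0.003, 0.9])

    def test_constant_p_gives_pi0_times_p(self):
        q, _ = qvalues(np.full(10, 0.2), pi0=0.5)
        np.testing.assert_allclose(q, 0.1)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q, _ = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_pi0_near_one_under_null(self):
        rng = np.random.default_rng(1)
        assert 0.8 <= estimate_pi0(rng.uniform(size=1000)) <= 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([0.1, 1.2]))


class TestAssignModules:
    def _modules(self):
        centroids = pd.DataFrame([[0.0, 0.0], [10.0, 10.0]], index=[1, 2],
                                 columns=["a", "b"])
        return ModuleSet(module_ids=[1, 2], centroids=centroids,
                         training_sizes={1: 30, 2: 30},
                         igp_values={1: 1.0, 2: 1.0},
                         p_values={1: 0.005, 2: 0.005},
                         q_values={1: 0.005, 2: 0.005}, pi0=1.0)

    def test_exact_centroid_match(self):
        data = pd.DataFrame([[10.0, 10.0]], columns=["a", "b"])
        out = assign_modules(data, self._modules())
        assert out["module"].iloc[0] == 2
        assert out["distance"].iloc[0] == 0.0

    def test_equidistant_tie_prefers_lower_module_id(self):
        data = pd.DataFrame([[5.0, 5.0]], columns=["a", "b"])
        assert assign_modules(data, self._modules())["module"].iloc[0] == 1

    def test_empty_module_set_rejected(self):
        ms = self._modules()
        ms.module_ids = []
        with pytest.raises(ValueError):
            assign_modules(pd.DataFrame([[0.0, 0.0]], columns=["a", "b"]), ms)

    def test_module_set_json_round_trip(self):
        ms = self._modules()
        back = ModuleSet.from_json(ms.to_json())
        assert back.module_ids == ms.module_ids
        pd.testing.assert_frame_equal(back.centroids, ms.centroids)
        assert back.q_values == ms.q_values
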