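"""Clustering methods, validation metrics (oracle-checked), score combination."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ktrquant import clustering as cl


# ---------------------------------------------------------------------------
# brute-force coordinate-space Ward oracle


def ward_oracle_merges(X):
    """Greedy Ward agglomeration: merge the pair with minimal SS increase.

    Returns the sequence of merged member-sets (frozensets of row indices),
    the classic minimum-variance merge order.
    """
    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best, best_pair = np.inf, None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            A = np.asarray(sorted(clusters[a]))
            B = np.asarray(sorted(clusters[b]))
            ma, mb = X[A].mean(axis=0), X[B].mean(axis=0)
            delta = len(A) * len(B) / (len(A) + len(B)) * ((ma - mb) ** 2).sum()
            if delta < best:
                best, best_pair = delta, (a, b)
        a, b = best_pair
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def scipy_merge_sets(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        merges.append(merged)
    return merges


class TestDistances:
    def test_manhattan_and_euclidean_examples(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0]])
        assert cl.pairwise_distances(X, "manhattan")[0, 1] == 3.0
        assert cl.pairwise_distances(X, "euclidean")[0, 1] == pytest.approx(np.sqrt(5))

    def test_identical_rows_zero_distance(self):
        X = np.ones((3, 4))
        assert cl.pairwise_distances(X).max() == 0.0

    def test_nan_rejected(self):
        X = np.array([[0.0, np.nan]])
        with pytest.raises(ValueError):
            cl.pairwise_distances(X)


class TestHierarchical:
    def test_toy_true_split(self, toy_points):
        X, true, _ = toy_points
        D = cl.pairwise_distances(X)
        res = cl.hierarchical_cluster(D, "ward2", k=2)
        assert adjusted_rand_score(true, res.labels) == 1.0
        # brute force: the true split minimizes within-cluster SS over all
        # 2-partitions
        best = None
        for assign in itertools.product([0, 1], repeat=4):
            if len(set(assign)) < 2:
                continue
            ss = sum(((X[np.array(assign) == c] -
                       X[np.array(assign) == c].mean(axis=0)) ** 2).sum()
                     for c in (0, 1))
            if best is None or ss < best[0]:
                best = (ss, assign)
        assert adjusted_rand_score(best[1], res.labels) == 1.0

    def test_k_equals_n_singletons(self, toy_points):
        X, _, _ = toy_points
        D = cl.pairwise_distances(X)
        res = cl.hierarchical_cluster(D, "ward", k=4)
        assert len(np.unique(res.labels)) == 4

    def test_k_out_of_range_rejected(self, toy_points):
        X, _, _ = toy_points
        D = cl.pairwise_distances(X)
        with pytest.raises(ValueError):
            cl.hierarchical_cluster(D, "ward2", k=5)

    @pytest.mark.parametrize("seed", range(10))
    def test_ward2_euclidean_matches_coordinate_ward_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        X = rng.normal(size=(n, 3))
        D = cl.pairwise_distances(X, "euclidean")
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        Z = linkage(squareform(D, checks=False), method="ward")
        assert scipy_merge_sets(Z, n) == ward_oracle_merges(X)

    def test_ward_and_ward2_differ_on_manhattan(self):
        # the two linkage variants are genuinely different procedures
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 4))
        D = cl.pairwise_distances(X, "manhattan")
        r1 = cl.hierarchical_cluster(D, "ward", k=5)
        r2 = cl.hierarchical_cluster(D, "ward2", k=5)
        assert r1.labels.shape == r2.labels.shape  # same contract either way


class TestKMeans:
    def test_toy_global_optimum(self, toy_points):
        X, true, _ = toy_points
        res = cl.kmeans_cluster(X, 2, seed=0)
        assert adjusted_rand_score(true, res.labels) == 1.0

    def test_k_one_total_ss(self, toy_points):
        X, _, _ = toy_points
        res = cl.kmeans_cluster(X, 1, seed=0)
        total_ss = ((X - X.mean(axis=0)) ** 2).sum()
        assert res.inertia == pytest.approx(total_ss)

    def test_fixed_seed_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 10))
        r1 = cl.kmeans_cluster(X, 4, seed=42)
        r2 = cl.kmeans_cluster(X, 4, seed=42)
        np.testing.assert_array_equal(r1.labels, r2.labels)


class TestMetricsOracles:
    def test_toy_instance_values(self, toy_points):
        X, true, crossed = toy_points
        D = cl.pairwise_distances(X)
        assert cl.bw_ratio(D, true) == pytest.approx(10.0, abs=1e-9)
        assert cl.dunn_index(D, true) == pytest.approx(9.0, abs=1e-9)
        sil = 0.5 * ((10.5 - 1) / 10.5 + (9.5 - 1) / 9.5)
        assert cl.avg_silhouette(D, true) == pytest.approx(sil, abs=1e-9)
        d = np.array([1.0, 10.0, 11.0, 9.0, 10.0, 1.0])
        ind = np.array([0.0, 1.0, 1.0, 1.0, 1.0, 0.0])
        pg = np.corrcoef(d, ind)[0, 1]
        assert cl.pearson_gamma(D, true) == pytest.approx(pg, abs=1e-9)
        assert cl.calinski_harabasz(X, true) == pytest.approx(200.0, abs=1e-9)
        assert cl.connectivity(D, true, L=1) == pytest.approx(0.0, abs=1e-9)
        assert cl.connectivity(D, crossed, L=1) == pytest.approx(4.0, abs=1e-9)

    def test_metrics_prefer_true_split_over_crossed(self, toy_points):
        X, true, crossed = toy_points
        D = cl.pairwise_distances(X)
        for metric in (cl.bw_ratio, cl.dunn_index, cl.avg_silhouette,
                       cl.pearson_gamma):
            assert metric(D, true) > metric(D, crossed)
        assert cl.calinski_harabasz(X, true) > cl.calinski_harabasz(X, crossed)
        assert cl.connectivity(D, true, L=2) < cl.connectivity(D, crossed, L=2)

    def test_label_permutation_invariance(self, toy_points):
        X, true, _ = toy_points
        D = cl.pairwise_distances(X)
        relabeled = np.where(true == 1, 7, 3)
        perm = np.array([2, 3, 0, 1])  # swap row order consistently
        Dp = D[np.ix_(perm, perm)]
        for metric in (cl.bw_ratio, cl.dunn_index, cl.avg_silhouette,
                       cl.pearson_gamma, cl.connectivity):
            assert metric(D, true) == pytest.approx(metric(D, relabeled))
            assert metric(D, true) == pytest.approx(metric(Dp, true[perm]))

    def test_degenerate_inputs_raise(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        D = cl.pairwise_distances(X)
        labels = np.array([1, 1, 2, 2])
        with pytest.raises(ValueError):  # duplicated points -> W = 0
            cl.bw_ratio(D, labels)
        with pytest.raises(ValueError):  # zero diameter
            cl.dunn_index(D, labels)
        with pytest.raises(ValueError):  # zero within-cluster variance
            cl.calinski_harabasz(X, labels)
        with pytest.raises(ValueError):  # constant distances
            cl.pearson_gamma(np.zeros((3, 3)), np.array([1, 1, 2]))
        with pytest.raises(ValueError):  # fewer than 2 clusters
            cl.dunn_index(D, np.ones(4))

    def test_perfect_two_block_metric_gamma_one(self):
        D = np.ones((6, 6)) - np.eye(6)
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        labels = np.array([1, 1, 1, 2, 2, 2])
        assert cl.pearson_gamma(D, labels) == pytest.approx(1.0)

    def test_random_labels_on_one_blob_bw_near_one(self):
        # under random labeling of a single Gaussian blob, between- and
        # within-cluster mean distances coincide in expectation
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(50):
            X = rng.normal(size=(40, 5))
            D = cl.pairwise_distances(X)
            labels = rng.permutation(np.repeat([1, 2], 20))
            vals.append(cl.bw_ratio(D, labels))
        assert abs(np.mean(vals) - 1.0) < 0.1

    def test_random_labels_silhouette_near_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(50):
            X = rng.normal(size=(40, 5))
            D = cl.pairwise_distances(X)
            labels = rng.permutation(np.repeat([1, 2], 20))
            vals.append(cl.avg_silhouette(D, labels))
        assert abs(np.mean(vals)) < 0.1

    def test_separated_clusters_zero_connectivity(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.1, size=(30, 2)),
                       rng.normal(100, 0.1, size=(30, 2))])
        D = cl.pairwise_distances(X)
        labels = np.repeat([1, 2], 30)
        assert cl.connectivity(D, labels, L=25) == 0.0

    def test_connectivity_improves_when_boundary_point_fixed(self):
        X = np.array([[0.0], [0.5], [1.0], [10.0], [10.5], [11.0]])
        D = cl.pairwise_distances(X)
        wrong = np.array([1, 1, 2, 2, 2, 2])   # point 2 misassigned
        fixed = np.array([1, 1, 1, 2, 2, 2])
        assert cl.connectivity(D, fixed, L=3) <= cl.connectivity(D, wrong, L=3)


class TestScoreCombination:
    def _report(self, rows):
        return pd.DataFrame(rows)

    def test_single_combination_scores_six(self):
        report = self._report([{
            "combination": "only", "k": 2, "bw": 3.0, "dunn": 1.0,
            "avg_silhouette": 0.5, "pearson_gamma": 0.8,
            "calinski_harabasz": 50.0, "connectivity": 2.0,
        }])
        out = cl.combine_metric_scores(report)
        assert out["combined_score"].iloc[0] == pytest.approx(6.0)
        norm_cols = [f"norm_{m}" for m in cl.METRIC_NAMES]
        np.testing.assert_allclose(out[norm_cols].iloc[0], 1.0)

    def test_dominant_combination_ranks_first_with_six(self):
        rows = [
            {"combination": "good", "k": 3, "bw": 4.0, "dunn": 2.0,
             "avg_silhouette": 0.9, "pearson_gamma": 0.9,
             "calinski_harabasz": 100.0, "connectivity": 1.0},
            {"combination": "bad", "k": 4, "bw": 2.0, "dunn": 1.0,
             "avg_silhouette": 0.4, "pearson_gamma": 0.5,
             "calinski_harabasz": 40.0, "connectivity": 5.0},
        ]
        out = cl.combine_metric_scores(self._report(rows))
        assert out.iloc[0]["combination"] == "good"
        assert out.iloc[0]["combined_score"] == pytest.approx(6.0)
        assert out.iloc[1]["combined_score"] < 6.0

    def test_ties_break_toward_fewer_clusters(self):
        row = {"bw": 1.0, "dunn": 1.0, "avg_silhouette": 0.5,
               "pearson_gamma": 0.5, "calinski_harabasz": 10.0,
               "connectivity": 1.0}
        rows = [{"combination": "k5", "k": 5, **row},
                {"combination": "k3", "k": 3, **row}]
        out = cl.combine_metric_scores(self._report(rows))
        assert out.iloc[0]["combination"] == "k3"

    def test_planted_archetypes_select_true_k(self):
        # 4 planted archetypes; the grid over k in {3,4,5} x 5 methods should
        # put k=4 on top for most seeds
        from ktrquant import synth, trajectories as tj
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            cfg = synth.SynthConfig(n_cells=40, noise_sd=0.02,
                                    amplitude_cv=0.0, seed=seed)
            arch = synth.default_archetypes()
            mix = [arch[a] for a in ("flat", "transient", "sustained", "biphasic")]
            tab = synth.generate_trajectories(cfg, mix)
            norm = tj.normalize_baseline(tab)
            matrix, _ = tj.trajectory_matrix(norm, "erk")
            scored, best, _ = cl.select_clustering(matrix, (3, 4, 5), seed=seed)
            hits += int(scored.iloc[0]["k"] == 4)
        assert hits / n_seeds >= 0.8


class TestGridAndRecovery:
    def test_grid_has_fifteen_combinations(self):
        assert len(cl.candidate_grid((8, 9, 10))) == 15
        assert len(cl.candidate_grid((3, 4, 5))) == 15

    def test_manhattan_ward2_recovers_planted_archetypes(self):
        from ktrquant import synth, trajectories as tj
        cfg = synth.SynthConfig(n_cells=60, noise_sd=0.05, amplitude_cv=0.0,
                                seed=13)
        arch = synth.default_archetypes()
        mix = [arch[a] for a in ("flat", "transient", "sustained", "biphasic")]
        tab = synth.generate_trajectories(cfg, mix)
        norm = tj.normalize_baseline(tab)
        matrix, cells = tj.trajectory_matrix(norm, "erk")
        truth = norm.groupby("cell_id")["truth_label"].first().loc[cells]
        D = cl.pairwise_distances(matrix, "manhattan")
        res = cl.hierarchical_cluster(D, "ward2", k=4, distance_name="manhattan")
        assert adjusted_rand_score(truth, res.labels) >= 0.9


class TestSummaries:
    def test_condition_distribution_sums_to_one(self):
        labels = np.array([1, 1, 2, 3, 3, 3])
        conds = ["ctrl", "ctrl", "ctrl", "stim", "stim", "stim"]
        frac = cl.cluster_condition_distribution(labels, conds)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)
        assert frac.loc["stim", 3] == pytest.approx(1.0)

    def test_cooccurrence_marginals_consistent(self):
        rng = np.random.default_rng(3)
        n = 300
        erk = rng.integers(1, 5, size=n)
        akt = rng.integers(1, 4, size=n)
        conds = rng.choice(["a", "b"], size=n)
        joint = cl.cluster_cooccurrence(erk, akt, conds)
        for cond in ("a", "b"):
            sub = joint[joint.condition == cond]
            marg_erk = sub.groupby("erk_cluster")["fraction"].sum()
            direct = cl.cluster_condition_distribution(
                erk[conds == cond], np.repeat(cond, (conds == cond).sum()))
            for c in marg_erk.index:
                assert marg_erk[c] == pytest.approx(direct.loc[cond, c])

    def test_perfectly_coupled_labels_mass_on_diagonal(self):
        labels = np.array([1, 2, 3, 1, 2, 3])
        joint = cl.cluster_cooccurrence(labels, labels, np.repeat("c", 6))
        off = joint[joint.erk_cluster != joint.akt_cluster]
        assert off.empty

    def test_mismatched_cell_sets_rejected(self):
        with pytest.raises(ValueError):
            cl.cluster_cooccurrence(np.array([1, 2]), np.array([1]), ["a"])
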