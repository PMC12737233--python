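"""Clustering algorithms, effect-size gate, quality indices, and selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitpheno.clustering import (
    ALGORITHMS,
    ClusterCondition,
    ClusterSolution,
    EffectSizeResult,
    MethodEvaluation,
    QualityIndices,
    effect_size,
    gate_condition,
    kmedoids,
    quality_indices,
    run_clustering,
    select_best,
)
from gaitpheno.config import GateConfig
from gaitpheno.types import DissimilarityMatrix, Embedding


def _dm_from_points(pts):
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    ids = list(range(len(pts)))
    return DissimilarityMatrix(D, ids), Embedding(pts, 0.0, ids)


class TestRunClustering:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_triplets(self, algorithm, rng):
        centers = np.array([[0, 0], [100, 0], [0, 100]], dtype=float)
        pts = np.vstack([c + rng.normal(0, 0.5, size=(3, 2)) for c in centers])
        D, E = _dm_from_points(pts)
        sol = run_clustering(D, E, ClusterCondition("pca", algorithm, 3), seed=0)
        expected = np.repeat([0, 1, 2], 3)
        # partitions must agree up to label permutation
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(expected, sol.labels) == 1.0

    def test_k_equals_n_medoids(self, rng):
        pts = rng.normal(size=(6, 2)) * 10
        D, E = _dm_from_points(pts)
        sol = run_clustering(D, E, ClusterCondition("pca", "kmedoids_pp", 6), seed=0)
        assert len(np.unique(sol.labels)) == 6

    def test_k_too_large_rejected(self, rng):
        pts = rng.normal(size=(4, 2))
        D, E = _dm_from_points(pts)
        with pytest.raises(ValueError, match="exceeds"):
            run_clustering(D, E, ClusterCondition("pca", "kmedoids_pp", 5), seed=0)

    def test_kmedoids_matches_exhaustive_search(self, rng):
        """Total within-cluster medoid cost equals the best over all medoid
        pairs on a handcrafted 6x6 distance matrix."""
        pts = rng.normal(size=(6, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = kmedoids(D, 2, seed=0, restarts=20)

        def cost_for_medoids(ms):
            return D[:, list(ms)].min(axis=1).sum()

        best = min(cost_for_medoids(ms) for ms in itertools.combinations(range(6), 2))
        # cost of the returned partition with per-cluster optimal medoids
        achieved = 0.0
        for c in np.unique(labels):
            members = np.where(labels == c)[0]
            achieved += D[np.ix_(members, members)].sum(axis=0).min()
        assert achieved == pytest.approx(best, abs=1e-10)


class TestEffectSize:
    def test_identical_groups_eta2_zero(self):
        vals = np.array([1.0, 2, 3, 1, 2, 3])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = effect_size(vals, labels)
        assert res.effect == pytest.approx(0.0, abs=1e-12)

    def test_all_variance_between(self, rng):
        vals = np.concatenate([rng.normal(0, 0.001, 10), rng.normal(10, 0.001, 10)])
        labels = np.repeat([0, 1], 10)
        assert effect_size(vals, labels).effect > 0.99

    def test_eta2_matches_ss_decomposition(self, rng):
        vals = rng.normal(size=60)
        labels = rng.integers(0, 3, 60)
        res = effect_size(vals, labels)
        if res.test_used == "anova_eta2":
            grand = vals.mean()
            ssb = sum(
                (labels == g).sum() * (vals[labels == g].mean() - grand) ** 2
                for g in np.unique(labels)
            )
            sst = ((vals - grand) ** 2).sum()
            assert res.effect == pytest.approx(ssb / sst, abs=1e-12)

    def test_epsilon2_identity(self, rng):
        """epsilon^2 = H/(N-1); the rank branch is forced by a tiny cluster."""
        vals = rng.normal(size=32)
        labels = np.array([0] * 15 + [1] * 15 + [2] * 2)
        res = effect_size(vals, labels)
        assert res.test_used == "kruskal_epsilon2"
        groups = [vals[labels == g] for g in np.unique(labels)]
        H = stats.kruskal(*groups).statistic
        assert res.effect == pytest.approx(H / (len(vals) - 1), abs=1e-12)

    def test_skewed_data_uses_rank_branch(self, rng):
        vals = np.exp(rng.normal(size=90) * 2)
        labels = rng.integers(0, 3, 90)
        assert effect_size(vals, labels).test_used == "kruskal_epsilon2"

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            effect_size(np.arange(5.0), np.zeros(5))


class TestGate:
    def _effects(self, values):
        names = list(GateConfig().key_parameters)
        return [EffectSizeResult(n, "anova_eta2", 0.0, v) for n, v in zip(names, values)]

    def test_exactly_four_passing(self):
        assert gate_condition(self._effects([0.2, 0.2, 0.2, 0.2, 0.05, 0.05, 0.05]),
                              GateConfig())

    def test_threshold_is_strict(self):
        assert not gate_condition(self._effects([0.14] * 7), GateConfig())

    def test_matches_bruteforce_counting(self, rng):
        gate = GateConfig()
        for _ in range(100):
            vals = rng.uniform(0, 0.3, 7)
            expected = (vals > 0.14).sum() >= 4
            assert gate_condition(self._effects(vals), gate) == expected

    def test_missing_parameter_rejected(self):
        effects = self._effects([0.2] * 7)[:-1]
        with pytest.raises(ValueError, match="missing"):
            gate_condition(effects, GateConfig())

    def test_monotone_in_effect_size(self, rng):
        """Raising any effect size never flips pass into fail."""
        gate = GateConfig()
        for _ in range(50):
            vals = rng.uniform(0, 0.3, 7)
            if gate_condition(self._effects(vals), gate):
                i = int(rng.integers(7))
                vals[i] += rng.uniform(0, 0.5)
                assert gate_condition(self._effects(vals), gate)


class TestQualityIndices:
    def test_balance_published_sizes(self, rng):
        """Cluster sizes (39, 34, 40, 33) give balance 7."""
        sizes = [39, 34, 40, 33]
        labels = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
        pts = np.concatenate(
            [rng.normal(10 * i, 1, size=(s, 2)) for i, s in enumerate(sizes)]
        )
        D, E = _dm_from_points(pts)
        q = quality_indices(D, E, ClusterSolution(ClusterCondition(k=4), labels))
        assert q.balance == 7

    def test_equal_sizes_balance_zero(self, rng):
        labels = np.repeat([0, 1], 5)
        pts = np.concatenate([rng.normal(0, 1, (5, 2)), rng.normal(9, 1, (5, 2))])
        D, E = _dm_from_points(pts)
        q = quality_indices(D, E, ClusterSolution(ClusterCondition(k=2), labels))
        assert q.balance == 0

    def test_silhouette_matches_manual_computation(self):
        """8-point toy: silhouette from the matrix equals the a/b definition."""
        pts = np.array(
            [[0, 0], [1, 0], [0, 1], [1, 1], [10, 10], [11, 10], [10, 11], [11, 11]],
            dtype=float,
        )
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        D, E = _dm_from_points(pts)
        q = quality_indices(D, E, ClusterSolution(ClusterCondition(k=2), labels))
        sil = []
        for i in range(8):
            same = [j for j in range(8) if labels[j] == labels[i] and j != i]
            other = [j for j in range(8) if labels[j] != labels[i]]
            a = np.mean([D.D[i, j] for j in same])
            b = np.mean([D.D[i, j] for j in other])
            sil.append((b - a) / max(a, b))
        assert q.silhouette == pytest.approx(np.mean(sil), abs=1e-10)


class TestSelectBest:
    def _ev(self, sil, db, bal, passed=True):
        return MethodEvaluation(
            ClusterCondition(k=4), passed, [], QualityIndices(sil, db, bal)
        )

    def test_dominating_condition_wins(self):
        a = self._ev(0.8, 0.3, 2)
        b = self._ev(0.5, 0.9, 10)
        assert select_best([a, b]) is a

    def test_single_passing_composite(self):
        a = self._ev(0.5, 1.0, 5)
        best = select_best([a, self._ev(0.9, 0.1, 0, passed=False)])
        assert best is a
        assert best.composite == pytest.approx(1.5)

    def test_matches_exhaustive_recomputation(self, rng):
        for _ in range(30):
            evs = [
                self._ev(rng.uniform(-0.2, 0.9), rng.uniform(0.1, 3), int(rng.integers(0, 30)))
                for _ in range(6)
            ]
            best = select_best(evs)
            sils = np.array([e.indices.silhouette for e in evs])
            dbs = np.array([e.indices.davies_bouldin for e in evs])
            bals = np.array([float(e.indices.balance) for e in evs])

            def norm(v):
                return (v - v.min()) / (v.max() - v.min()) if np.ptp(v) > 0 else np.full(len(v), 0.5)

            comp = norm(sils) + (1 - norm(dbs)) + (1 - norm(bals))
            assert best.composite == pytest.approx(comp.max(), abs=1e-12)

    def test_ranking_invariant_to_affine_index_rescale(self, rng):
        evs = [
            self._ev(rng.uniform(0, 0.9), rng.uniform(0.1, 3), int(rng.integers(0, 30)))
            for _ in range(5)
        ]
        base_best = select_best(evs).indices.silhouette
        scaled = [
            self._ev(e.indices.silhouette, 2.0 * e.indices.davies_bouldin + 3.0,
                     e.indices.balance)
            for e in evs
        ]
        assert select_best(scaled).indices.silhouette == base_best

    def test_no_passing_condition_raises(self):
        with pytest.raises(ValueError, match="no admissible method"):
            select_best([self._ev(0.5, 0.5, 3, passed=False)])
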