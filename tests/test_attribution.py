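"""Attribution exactness, tie-averaged ranking, and weighted Borda consensus."""

import itertools
import math

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from gaitpheno.attribution import (
    _sklearn_tree_arrays,
    positive_class_attributions,
    rank_with_ties,
    sampling_shap_values,
    tree_shap_values,
    weighted_borda,
)


def _expvalue(tr, x, S, node=0):
    """Cover-weighted conditional expectation of the tree output given the
    features in S (the value function of path-dependent tree Shapley)."""
    if tr["left"][node] < 0:
        return tr["value"][node]
    d = tr["feature"][node]
    l, r = tr["left"][node], tr["right"][node]
    if d in S:
        return _expvalue(tr, x, S, l if x[d] <= tr["threshold"][node] else r)
    cl, cr = tr["cover"][l], tr["cover"][r]
    return (cl * _expvalue(tr, x, S, l) + cr * _expvalue(tr, x, S, r)) / (cl + cr)


def _brute_shapley(tr, x, n_feat):
    phi = np.zeros(n_feat)
    for i in range(n_feat):
        rest = [f for f in range(n_feat) if f != i]
        for r in range(len(rest) + 1):
            for S in itertools.combinations(rest, r):
                w = (
                    math.factorial(len(S))
                    * math.factorial(n_feat - len(S) - 1)
                    / math.factorial(n_feat)
                )
                phi[i] += w * (_expvalue(tr, x, set(S) | {i}) - _expvalue(tr, x, set(S)))
    return phi


class TestTreeShap:
    def test_stump_puts_all_mass_on_split_feature(self, rng):
        X = rng.normal(size=(50, 4))
        y = (X[:, 2] > 0).astype(int)
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        vals, _ = tree_shap_values(tree, X[:10])
        assert np.allclose(vals[:, [0, 1, 3]], 0.0)
        assert np.any(vals[:, 2] != 0.0)

    def test_constant_model_zero_attributions(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.zeros(30, dtype=int)
        y[0] = 1  # two classes but a pure-majority stump after no split
        tree = DecisionTreeClassifier(max_depth=1, min_samples_leaf=30, random_state=0)
        tree.fit(X, y)
        vals, base = tree_shap_values(tree, X[:5])
        assert np.allclose(vals, 0.0)

    def test_matches_exhaustive_shapley_enumeration(self, rng):
        """Depth-2 trees on 3 binary features equal the 2^d coalition oracle."""
        for trial in range(4):
            X = rng.integers(0, 2, size=(60, 3)).astype(float)
            y = rng.integers(0, 2, 60)
            tree = DecisionTreeClassifier(max_depth=2, random_state=trial).fit(X, y)
            tr = _sklearn_tree_arrays(tree)
            vals, base = tree_shap_values(tree, X[:6])
            for i in range(6):
                assert np.allclose(vals[i], _brute_shapley(tr, X[i], 3), atol=1e-9)

    def test_local_accuracy_random_forest(self, rng):
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        attr = positive_class_attributions(rf, X[:10], "random_forest", list("abcde"))
        out = attr.values.sum(axis=1) + attr.base_values
        assert np.allclose(out, rf.predict_proba(X[:10])[:, 1], atol=1e-6)

    def test_local_accuracy_xgboost(self, rng):
        from xgboost import XGBClassifier

        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        model = XGBClassifier(n_estimators=30, max_depth=3, random_state=0).fit(X, y)
        attr = positive_class_attributions(
            model, X[:10], "gradient_boosted_trees", list("abcd")
        )
        margins = model.predict(X[:10], output_margin=True)
        assert np.allclose(attr.values.sum(axis=1) + attr.base_values, margins, atol=1e-4)

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            positive_class_attributions(
                DecisionTreeClassifier(), np.zeros((2, 2)), "decision_tree", ["a", "b"]
            )


class TestSamplingShap:
    def test_additivity_is_exact(self, rng):
        """Telescoping over each permutation makes base + sum(attributions)
        equal the prediction exactly, despite sampling."""
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] - X[:, 3] > 0).astype(int)
        mlp = MLPClassifier(hidden_layer_sizes=(10,), max_iter=500, random_state=0)
        mlp.fit(X, y)
        f = lambda Z: mlp.predict_proba(Z)[:, 1]
        vals, base = sampling_shap_values(f, X[:5], X[:15], n_permutations=8, seed=0)
        assert np.allclose(vals.sum(axis=1) + base, f(X[:5]), atol=1e-10)

    def test_linear_model_recovers_exact_shapley(self, rng):
        """For a linear function the Shapley value is beta_i (x_i - mean(bg_i))
        for any permutation, so the sampling estimator is exact."""
        beta = np.array([2.0, -1.0, 0.5])
        f = lambda Z: Z @ beta
        X = rng.normal(size=(4, 3))
        bg = rng.normal(size=(10, 3))
        vals, base = sampling_shap_values(f, X, bg, n_permutations=4, seed=1)
        expected = beta * (X - bg.mean(axis=0))
        assert np.allclose(vals, expected, atol=1e-10)


class TestRankWithTies:
    def test_tie_average_example(self):
        assert np.allclose(rank_with_ties([0.5, 0.3, 0.3, 0.1]), [1, 2.5, 2.5, 4])

    def test_all_equal(self):
        assert np.allclose(rank_with_ties([0.2] * 5), [3.0] * 5)

    def test_matches_sort_and_average_oracle(self, rng):
        for _ in range(30):
            v = rng.choice([0.0, 0.1, 0.2, 0.5, 0.9], size=10)
            ranks = rank_with_ties(v)
            # oracle: positions in descending sort, averaged over ties
            order = np.argsort(-v, kind="stable")
            pos = np.empty(10)
            pos[order] = np.arange(1, 11)
            expected = np.array([pos[v == x].mean() for x in v])
            assert np.allclose(ranks, expected)

    def test_negative_importance_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            rank_with_ties([0.1, -0.2])


class TestWeightedBorda:
    def test_single_model_formula(self):
        """One model, weight 1, a rank-1 feature among n=5: S = n - 1 + 1 = 5."""
        res = weighted_borda(np.array([[1.0], [2], [3], [4], [5]]), np.array([1.0]))
        assert res.scores[0] == pytest.approx(5.0)
        assert np.allclose(res.scores, [5, 4, 3, 2, 1])

    def test_matches_bruteforce_summation(self, rng):
        for _ in range(20):
            n, k = int(rng.integers(3, 12)), int(rng.integers(2, 5))
            base = np.tile(np.arange(1.0, n + 1)[:, None], (1, k))
            R = np.take_along_axis(
                base, rng.permuted(np.tile(np.arange(n)[:, None], (1, k)), axis=0), axis=0
            )
            w = rng.uniform(0.5, 1.0, k)
            res = weighted_borda(R, w)
            brute = [
                sum(w[j] * (n - R[i, j] + 1) for j in range(k)) for i in range(n)
            ]
            assert np.allclose(res.scores, brute)

    def test_rank_reversal_antisymmetry(self, rng):
        n, k = 8, 3
        R = np.column_stack([rng.permutation(n) + 1.0 for _ in range(k)])
        w = rng.uniform(0.5, 1.0, k)
        fwd = weighted_borda(R, w).scores
        rev = weighted_borda(n + 1 - R, w).scores
        # reversing every ranking mirrors the scores about the midpoint,
        # hence exactly reverses the Borda ordering
        assert np.allclose(fwd + rev, (n + 1) * w.sum())

    def test_scale_equivariance(self, rng):
        R = np.column_stack([rng.permutation(6) + 1.0 for _ in range(4)])
        w = rng.uniform(0.5, 1.0, 4)
        s1 = weighted_borda(R, w).scores
        s3 = weighted_borda(R, 3.0 * w).scores
        assert np.allclose(s3, 3.0 * s1)

    def test_unanimous_top_feature_attains_bound(self):
        R = np.array([[1.0, 1, 1], [2, 3, 2], [3, 2, 3]])
        w = np.array([0.9, 0.8, 0.7])
        res = weighted_borda(R, w)
        assert res.scores[0] == pytest.approx(3 * w.sum())
        assert res.ordering[0] == 0

    def test_out_of_range_rank_rejected(self):
        with pytest.raises(ValueError, match="ranks must lie"):
            weighted_borda(np.array([[0.5], [2.0]]), np.array([1.0]))
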