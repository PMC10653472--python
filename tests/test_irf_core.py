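import numpy as np
import pytest

from multiview_irf.irf_core import (
    ForestParams,
    RitParams,
    SignedItemset,
    TreeArrays,
    WeightedForest,
    bagged_stability,
    encode_item,
    extract_signed_itemsets,
    fit_weighted_forest,
    gini_importance,
    iterate_reweighted_forest,
    run_rit,
)


def _signal_data(n=200, p=30, seed=0, flip=0.1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = ((X[:, 0] > 0) & (X[:, 1] > 0)).astype(int)
    noise = rng.random(n) < flip
    return X, np.where(noise, 1 - y, y)


class TestFitWeightedForest:
    def test_separable_training_accuracy(self, separable_data):
        X, y = separable_data
        forest = fit_weighted_forest(X, y, None, ForestParams(n_trees=30, seed=1))
        assert np.array_equal(forest.predict_proba(X) > 0.5, y.astype(bool))

    def test_single_nonzero_weight_forces_feature(self):
        X, y = _signal_data(seed=2)
        w = np.zeros(X.shape[1])
        w[4] = 1.0
        forest = fit_weighted_forest(X, y, w, ForestParams(n_trees=10, seed=3))
        for tree in forest.trees:
            used = tree.feature[tree.feature >= 0]
            assert np.all(used == 4)

    def test_zero_weight_feature_never_used_importance_zero(self):
        X, y = _signal_data(seed=4)
        w = np.ones(X.shape[1])
        w[7] = 0.0
        forest = fit_weighted_forest(X, y, w, ForestParams(n_trees=20, seed=5))
        assert forest.importances[7] == 0.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError, match="binary"):
            fit_weighted_forest(X, np.zeros(10, dtype=int))

    def test_all_zero_weights_rejected(self):
        X, y = _signal_data()
        with pytest.raises(ValueError, match="all zero"):
            fit_weighted_forest(X, y, np.zeros(X.shape[1]))

    def test_determinism(self):
        X, y = _signal_data(seed=6)
        a = fit_weighted_forest(X, y, None, ForestParams(n_trees=10, seed=7))
        b = fit_weighted_forest(X, y, None, ForestParams(n_trees=10, seed=7))
        assert np.array_equal(a.predict_proba(X), b.predict_proba(X))
        assert np.array_equal(a.importances, b.importances)

    def test_min_node_respected(self):
        X, y = _signal_data(seed=8)
        forest = fit_weighted_forest(X, y, None, ForestParams(n_trees=10, min_node=10, seed=9))
        for tree in forest.trees:
            leaves = tree.feature < 0
            # only count reachable leaves (allocated nodes)
            counts = tree.count0[leaves] + tree.count1[leaves]
            assert counts.min() >= 10

    def test_max_depth_cap(self):
        X, y = _signal_data(seed=10)
        forest = fit_weighted_forest(X, y, None, ForestParams(n_trees=5, max_depth=2, seed=11))
        for tree in forest.trees:
            # depth <= 2 means at most 7 nodes
            assert len(tree.feature) <= 7


class TestGiniImportance:
    def test_traversal_oracle(self):
        X, y = _signal_data(n=20, p=6, seed=12)
        forest = fit_weighted_forest(X, y, None, ForestParams(n_trees=15, seed=13))
        imp = gini_importance(forest)
        # independent re-summation of stored per-node decreases
        oracle = np.zeros(6)
        for tree in forest.trees:
            for node in range(len(tree.feature)):
                if tree.feature[node] >= 0:
                    oracle[tree.feature[node]] += tree.decrease[node]
        oracle /= len(forest.trees)
        assert np.allclose(imp, oracle, atol=1e-12)

    def test_permutation_equivariance(self):
        # exact equivariance requires every feature to be a candidate at
        # every split (mtry = p; position-based mtry-subsets cannot commute
        # with a permutation) and tie-free splits (stumps on large nodes;
        # small nodes regularly produce exactly tied count-based decreases,
        # and no fixed tie-break can commute with a permutation)
        X, y = _signal_data(n=200, p=12, seed=14)
        perm = np.random.default_rng(15).permutation(12)
        params = ForestParams(n_trees=50, mtry=12, max_depth=1, seed=16)
        imp = gini_importance(fit_weighted_forest(X, y, None, params))
        imp_perm = gini_importance(fit_weighted_forest(X[:, perm], y, None, params))
        assert np.allclose(imp_perm, imp[perm], atol=1e-12)

    def test_stump_hand_computation(self):
        # 8 samples, perfect split: decrease = 8*0.5 - 4*0 - 4*0 = 4.0
        X = np.array([[-1.0]] * 4 + [[1.0]] * 4)
        y = np.array([0] * 4 + [1] * 4)
        forest = fit_weighted_forest(
            X, y, None, ForestParams(n_trees=1, seed=17, in_tree_bootstrap=False)
        )
        assert gini_importance(forest)[0] == pytest.approx(4.0, abs=1e-12)

    def test_conservation_identity(self):
        # per-tree sum of decreases telescopes to root minus leaf impurity
        X, y = _signal_data(n=60, p=8, seed=18)
        forest = fit_weighted_forest(X, y, None, ForestParams(n_trees=10, seed=19))
        for tree in forest.trees:
            def wgini(n0, n1):
                n = n0 + n1
                return 0.0 if n == 0 else n - (n0**2 + n1**2) / n

            total_dec = tree.decrease[tree.feature >= 0].sum()
            root = wgini(tree.count0[0], tree.count1[0])
            leaves = tree.feature < 0
            leaf_imp = sum(
                wgini(c0, c1) for c0, c1 in zip(tree.count0[leaves], tree.count1[leaves])
            )
            assert total_dec == pytest.approx(root - leaf_imp, abs=1e-9)


class TestIterateReweighted:
    def test_k1_equals_plain_forest(self, separable_data):
        X, y = separable_data
        params = ForestParams(n_trees=20, seed=20)
        plain = fit_weighted_forest(X, y, None, params)
        iterated, history = iterate_reweighted_forest(X, y, 1, params)
        assert np.array_equal(plain.predict_proba(X), iterated.predict_proba(X))
        assert np.array_equal(plain.importances, iterated.importances)
        assert len(history) == 1 and np.allclose(history[0], 1.0 / X.shape[1])

    def test_weight_concentration_increases(self):
        # 2 strong features out of 100: planted weight mass grows with k
        gains = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((150, 100))
            y = ((X[:, 0] + X[:, 1] > 0)).astype(int)
            if len(np.unique(y)) < 2:
                continue
            _, history = iterate_reweighted_forest(
                X, y, 3, ForestParams(n_trees=50, seed=seed)
            )
            mass = [h[:2].sum() for h in history]
            gains.append(mass[-1] > mass[0])
        assert np.median(gains) == 1.0

    def test_k_must_be_positive(self):
        X, y = _signal_data()
        with pytest.raises(ValueError, match="K"):
            iterate_reweighted_forest(X, y, 0)


class TestSignedItemsets:
    def _manual_tree(self):
        # depth-2 tree: root splits f3 (>0 right); right child splits f1
        #        0:f3
        #   1(leaf)   2:f1
        #          3(leaf) 4(leaf)
        return TreeArrays(
            feature=np.array([3, -1, 1, -1, -1]),
            threshold=np.array([0.0, 0.0, 0.5, 0.0, 0.0]),
            left=np.array([1, -1, 3, -1, -1]),
            right=np.array([2, -1, 4, -1, -1]),
            count0=np.array([5, 3, 2, 2, 0]),
            count1=np.array([5, 0, 5, 1, 4]),
            decrease=np.array([2.0, 0.0, 1.0, 0.0, 0.0]),
        )

    def _forest_of(self, trees, p=6):
        return WeightedForest(trees, np.full(p, 1.0 / p), p, ForestParams(n_trees=len(trees)))

    def test_depth_one_itemset(self):
        tree = TreeArrays(
            feature=np.array([3, -1, -1]),
            threshold=np.array([0.0, 0.0, 0.0]),
            left=np.array([1, -1, -1]),
            right=np.array([2, -1, -1]),
            count0=np.array([4, 4, 0]),
            count1=np.array([4, 0, 4]),
            decrease=np.array([4.0, 0.0, 0.0]),
        )
        forest = self._forest_of([tree])
        X = np.zeros((6, 6))
        X[:4, 3] = 1.0  # four rows take the right (f3 > 0) branch
        y = np.array([1, 1, 1, 0, 1, 0])
        itemsets = extract_signed_itemsets(forest, X, y)
        right = [s for s in itemsets if s.items == frozenset({encode_item(3, 1)})]
        assert len(right) == 1 and right[0].weight == 3

    def test_no_class1_rows_empty(self):
        forest = self._forest_of([self._manual_tree()])
        X = np.zeros((3, 6))
        y = np.zeros(3, dtype=int)
        assert extract_signed_itemsets(forest, X, y) == []

    def test_paths_match_recursive_oracle(self):
        X, y = _signal_data(n=40, p=6, seed=21)
        forest = fit_weighted_forest(X, y, None, ForestParams(n_trees=5, seed=22))
        got = {(s.items, s.weight) for s in extract_signed_itemsets(forest, X, y)}

        # independent recursive tree walk
        expected = set()
        for tree in forest.trees:
            def leaf_of(row):
                node = 0
                while tree.feature[node] >= 0:
                    node = (
                        tree.left[node]
                        if row[tree.feature[node]] <= tree.threshold[node]
                        else tree.right[node]
                    )
                return node

            def walk(node, path):
                if tree.feature[node] < 0:
                    count = sum(
                        1 for i in range(len(y)) if y[i] == 1 and leaf_of(X[i]) == node
                    )
                    if count > 0 and path:
                        dedup = {}
                        for f, s in reversed(path):  # deepest first
                            dedup.setdefault(f, s)
                        expected.add(
                            (frozenset(encode_item(f, s) for f, s in dedup.items()), count)
                        )
                    return
                f = tree.feature[node]
                walk(tree.left[node], path + [(f, -1)])
                walk(tree.right[node], path + [(f, 1)])

            walk(0, [])
        assert got == expected


class TestRunRit:
    def test_identical_itemsets_closure(self):
        items = frozenset({encode_item(1, 1), encode_item(2, -1)})
        out = run_rit([SignedItemset(items, 2)] * 5, RitParams(n_rit_trees=50), seed=1)
        assert out == [items]

    def test_disjoint_itemsets_yield_nothing(self):
        sets = [
            SignedItemset(frozenset({encode_item(i, 1), encode_item(i + 10, 1)}), 1)
            for i in range(5)
        ]
        assert run_rit(sets, RitParams(n_rit_trees=100), seed=2) == []

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            run_rit([], RitParams(), seed=0)

    def test_planted_pair_recovery_matches_enumeration_oracle(self):
        pair = frozenset({encode_item(0, 1), encode_item(1, 1)})
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            sets = []
            for _ in range(25):
                extra = {
                    encode_item(int(f), 1)
                    for f in rng.choice(np.arange(2, 10), size=2, replace=False)
                }
                if rng.random() < 0.9:
                    sets.append(SignedItemset(pair | extra, 1))
                else:
                    sets.append(SignedItemset(frozenset(extra), 1))
            out = run_rit(sets, RitParams(), seed=seed)

            # enumeration oracle: pair must be the unique maximal set with
            # prevalence >= 0.5 among all signed-item subsets
            from itertools import combinations

            universe = sorted(set().union(*[s.items for s in sets]))
            frequent = []
            for r in (2, 3):
                for cand in combinations(universe, r):
                    cs = frozenset(cand)
                    prev = sum(s.weight for s in sets if cs <= s.items) / len(sets)
                    if prev >= 0.5:
                        frequent.append(cs)
            maximal = [
                f for f in frequent if not any(f < g for g in frequent)
            ]
            assert maximal == [pair]
            hits += pair in out
        assert hits >= 38  # >= 95% of seeds

    def test_determinism(self):
        sets = [
            SignedItemset(frozenset({encode_item(0, 1), encode_item(1, 1), encode_item(i, -1)}), 1)
            for i in range(3, 8)
        ]
        assert run_rit(sets, seed=5) == run_rit(sets, seed=5)


class TestBaggedStability:
    def test_b1_stability_is_one(self):
        X, y = _signal_data(n=100, p=10, seed=23)
        out = bagged_stability(
            X, y, np.ones(10) / 10, 1, ForestParams(n_trees=20, seed=0),
            RitParams(n_rit_trees=50), seed=3,
        )
        assert all(it.stability == 1.0 for it in out)

    def test_stability_range_and_order(self):
        X, y = _signal_data(n=120, p=10, seed=24)
        out = bagged_stability(
            X, y, np.ones(10) / 10, 5, ForestParams(n_trees=20, seed=0),
            RitParams(n_rit_trees=100), seed=4,
        )
        stabs = [it.stability for it in out]
        assert all(0.0 <= s <= 1.0 for s in stabs)
        assert stabs == sorted(stabs, reverse=True)

    def test_planted_pair_outranks_spurious(self):
        wins = 0
        total = 0
        for seed in range(6):
            rng = np.random.default_rng(300 + seed)
            X = rng.standard_normal((150, 12))
            y = ((X[:, 0] > 0) & (X[:, 1] > 0)).astype(int)
            if y.sum() < 10:
                continue
            w = np.ones(12) / 12
            out = bagged_stability(
                X, y, w, 5, ForestParams(n_trees=40, seed=seed),
                RitParams(n_rit_trees=200), seed=seed,
            )
            if not out:
                continue
            total += 1
            pair = frozenset({encode_item(0, 1), encode_item(1, 1)})
            by_items = {it.items: it.stability for it in out}
            pair_stab = by_items.get(pair, 0.0)
            best_other = max(
                (s for items, s in by_items.items() if items != pair), default=0.0
            )
            wins += pair_stab >= best_other
        assert total >= 4 and wins / total >= 0.8


class TestJsonRoundTrip:
    def test_dump_load_identical(self, separable_data):
        X, y = separable_data
        forest = fit_weighted_forest(X, y, None, ForestParams(n_trees=5, seed=30))
        clone = WeightedForest.from_json(forest.to_json())
        assert np.array_equal(forest.predict_proba(X), clone.predict_proba(X))
        assert np.array_equal(forest.importances, clone.importances)
        assert clone.params == forest.params
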