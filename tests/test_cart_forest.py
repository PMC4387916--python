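import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import xrf
from xrf import Dataset, Hyperparameters
from xrf.cart_forest import UniformSampler, best_split, gini_impurity, gini_split, grow_tree

from conftest import assemble_model, constant_tree


# ---------------------------------------------------------------------------
# independent brute-force split enumerator (the oracle)


def brute_force_best_split(rows, candidates, data):
    """Enumerate every (feature, cut) pair and pick the minimal weighted gini.

    Ties: lowest feature, then smallest cut — the documented convention.
    """
    rows = np.asarray(rows)
    y = data.y[rows]
    n = len(rows)
    c = data.n_classes

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        _, counts = np.unique(labels, return_counts=True)
        p = counts / len(labels)
        return 1.0 - float((p**2).sum())

    best = None
    for f in sorted(set(int(j) for j in candidates)):
        v = data.X[rows, f]
        if data.feature_kinds[f] == "categorical":
            cuts = [(code, v == code) for code in np.unique(v)]
        else:
            sv = np.unique(v)
            cuts = []
            for lo, hi in zip(sv[:-1], sv[1:]):
                thr = 0.5 * (lo + hi)
                if thr >= hi:
                    thr = lo
                cuts.append((thr, v <= thr))
        for cut, mask in cuts:
            nl = int(mask.sum())
            if nl == 0 or nl == n:
                continue
            g = (nl * gini(y[mask]) + (n - nl) * gini(y[~mask])) / n
            if best is None or g < best[2] - 1e-12:
                best = (f, float(cut), g)
    return best


def random_fixture(rng, max_n=12, max_m=4):
    n = int(rng.integers(2, max_n + 1))
    m = int(rng.integers(1, max_m + 1))
    c = int(rng.integers(2, 4))
    # small integer grid provokes duplicate values and gini ties
    X = rng.integers(0, 5, size=(n, m)).astype(float)
    y = rng.integers(0, c, size=n)
    if len(np.unique(y)) < 2:
        y[0] = (y[0] + 1) % c
    return Dataset.from_arrays(X, y)


# ---------------------------------------------------------------------------


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected",
        [([5, 0], 0.0), ([3, 3], 0.5), ([1, 2], 4.0 / 9.0), ([1, 1, 1], 2.0 / 3.0)],
    )
    def test_known_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity([0, 0])

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=6).filter(lambda c: sum(c) > 0))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_bounds(self, counts):
        c = len(counts)
        g = gini_impurity(counts)
        assert 0.0 <= g <= 1.0 - 1.0 / c + 1e-12

    @pytest.mark.parametrize(
        "parent,left,right,expected",
        [
            ([2, 2], [2, 0], [0, 2], 0.0),
            ([2, 2], [1, 1], [1, 1], 0.5),
            ([2, 2], [2, 1], [0, 1], 1.0 / 3.0),
        ],
    )
    def test_split_values(self, parent, left, right, expected):
        assert gini_split(parent, left, right) == pytest.approx(expected, abs=1e-12)

    def test_split_empty_child_rejected(self):
        with pytest.raises(ValueError):
            gini_split([2, 2], [2, 2], [0, 0])

    def test_split_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            gini_split([2, 2], [2, 0], [1, 1])


class TestBestSplit:
    def test_perfect_numeric_split(self, separable_dataset):
        f, cut, g = best_split([0, 1, 2, 3], [0, 1], separable_dataset)
        assert (f, cut, g) == (0, 5.5, 0.0)

    def test_constant_features_give_none(self):
        data = Dataset.from_arrays(np.ones((4, 2)), [0, 0, 1, 1])
        assert best_split([0, 1, 2, 3], [0, 1], data) is None

    def test_empty_candidates_rejected(self, separable_dataset):
        with pytest.raises(ValueError):
            best_split([0, 1, 2, 3], [], separable_dataset)

    def test_categorical_one_vs_rest(self):
        X = np.array([[0.0], [0.0], [1.0], [2.0]])
        data = Dataset.from_arrays(X, [0, 0, 1, 1], feature_kinds=["categorical"])
        f, cut, g = best_split([0, 1, 2, 3], [0], data)
        assert f == 0 and cut == 0.0 and g == 0.0

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            data = random_fixture(rng)
            cands = list(range(data.n_features))
            got = best_split(np.arange(data.n_samples), cands, data)
            want = brute_force_best_split(np.arange(data.n_samples), cands, data)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got[2] == pytest.approx(want[2], abs=1e-12)
                assert (got[0], got[1]) == (want[0], want[1])

    def test_chosen_split_never_exceeds_parent_impurity(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            data = random_fixture(rng)
            rows = np.arange(data.n_samples)
            parent = gini_impurity(np.bincount(data.y, minlength=data.n_classes))
            got = best_split(rows, list(range(data.n_features)), data)
            if got is not None:
                assert got[2] <= parent + 1e-12


class TestGrowTree:
    def test_nmin_equal_bag_size_gives_stump(self, separable_dataset):
        sampler = UniformSampler(2, 2)
        tree = grow_tree([0, 1, 2, 3], separable_dataset, sampler, n_min=4, tree_seed=1)
        assert tree.node_count == 1 and tree.root.is_leaf
        assert tree.root.leaf_class == 0  # majority tie -> smallest class

    def test_pure_bag_gives_leaf(self, separable_dataset):
        sampler = UniformSampler(2, 2)
        tree = grow_tree([0, 0, 1], separable_dataset, sampler, n_min=1, tree_seed=1)
        assert tree.node_count == 1 and tree.root.leaf_class == 0

    def test_separable_bag_fit_perfectly(self, separable_dataset):
        sampler = UniformSampler(2, 2)
        tree = grow_tree([0, 1, 2, 3], separable_dataset, sampler, n_min=1, tree_seed=3)
        model = assemble_model([tree], [[0, 1, 2, 3]], ["a", "b"], n_features=2)
        preds = xrf.predict(model, separable_dataset)
        assert preds.tolist() == ["a", "a", "b", "b"]

    def test_node_invariants(self, noisy_separable):
        sampler = UniformSampler(3, noisy_separable.n_features)
        tree = grow_tree(np.arange(60), noisy_separable, sampler, n_min=1, tree_seed=9)
        c = noisy_separable.n_classes
        for i in range(tree.node_count):
            node = tree.node(i)
            assert node.class_counts.sum() == node.n_samples
            assert 0.0 <= node.impurity <= 1.0 - 1.0 / c + 1e-12
            assert node.is_leaf == (node.leaf_class is not None)


class TestFitForest:
    def test_seed_determinism(self, noisy_separable):
        h = Hyperparameters(n_trees=4, seed=11)
        m1 = xrf.fit_forest(noisy_separable, h)
        m2 = xrf.fit_forest(noisy_separable, h)
        assert all(a == b for a, b in zip(m1.trees, m2.trees))
        assert all(np.array_equal(a, b) for a, b in zip(m1.bag_indices, m2.bag_indices))

    def test_different_seeds_differ(self, noisy_separable):
        m1 = xrf.fit_forest(noisy_separable, Hyperparameters(n_trees=2, seed=1))
        m2 = xrf.fit_forest(noisy_separable, Hyperparameters(n_trees=2, seed=2))
        assert not np.array_equal(m1.bag_indices[0], m2.bag_indices[0])

    def test_oob_fraction_near_e_inverse(self):
        # E[|OOB|]/N = (1 - 1/N)^N -> 1/e
        rng = np.random.default_rng(3)
        data = Dataset.from_arrays(rng.standard_normal((1000, 2)), np.arange(1000) % 2)
        model = xrf.fit_forest(data, Hyperparameters(n_trees=10, seed=3))
        fracs = [1.0 - len(np.unique(bag)) / 1000 for bag in model.bag_indices]
        assert np.mean(fracs) == pytest.approx(np.exp(-1), abs=0.03)

    def test_separable_forest_low_oob_error(self, noisy_separable):
        model = xrf.fit_forest(noisy_separable, Hyperparameters(n_trees=100, seed=5))
        assert xrf.oob_error(model, noisy_separable) < 0.1


class TestVotingAndOob:
    def test_unanimous_vote(self, separable_dataset):
        trees = [constant_tree(0, 4, [2, 2]) for _ in range(3)]
        model = assemble_model(trees, [[0, 1, 2, 3]] * 3, ["a", "b"], n_features=2)
        assert xrf.predict(model, separable_dataset).tolist() == ["a"] * 4

    def test_majority_two_to_one(self, separable_dataset):
        trees = [constant_tree(0, 4, [2, 2]), constant_tree(0, 4, [2, 2]),
                 constant_tree(1, 4, [2, 2])]
        model = assemble_model(trees, [[0, 1, 2, 3]] * 3, ["a", "b"], n_features=2)
        assert xrf.predict(model, separable_dataset).tolist() == ["a"] * 4

    def test_single_tree_forest_equals_tree(self, noisy_separable):
        model = xrf.fit_forest(noisy_separable, Hyperparameters(n_trees=1, seed=2))
        votes = xrf.vote_matrix(model, noisy_separable)
        assert (votes.sum(axis=1) == 1).all()

    def test_vote_rows_sum_to_contributing_trees(self, noisy_separable):
        model = xrf.fit_forest(noisy_separable, Hyperparameters(n_trees=7, seed=2))
        votes = xrf.vote_matrix(model, noisy_separable)
        assert (votes.sum(axis=1) == 7).all()
        oob_votes = xrf.vote_matrix(model, noisy_separable, oob_only=True)
        n_oob_trees = model.oob_masks(60).sum(axis=0)
        assert np.array_equal(oob_votes.sum(axis=1), n_oob_trees)

    def test_oob_error_hand_fixture(self):
        # 4 samples, labels [a, a, b, b]; three constant trees with known bags.
        # tree0 predicts a, OOB {2, 3}; tree1 predicts b, OOB {0, 1};
        # tree2 predicts a, OOB {1, 3}.
        # OOB votes: s0 {b}->b wrong; s1 {b,a}->tie->a right; s2 {a}->a wrong;
        # s3 {a,a}->a wrong  => error 3/4.
        data = Dataset.from_arrays(np.arange(8, dtype=float).reshape(4, 2), ["a", "a", "b", "b"])
        trees = [constant_tree(0, 4, [2, 2]), constant_tree(1, 4, [2, 2]),
                 constant_tree(0, 4, [2, 2])]
        bags = [[0, 1, 0, 1], [2, 3, 2, 3], [0, 2, 0, 2]]
        model = assemble_model(trees, bags, ["a", "b"], n_features=2)
        assert xrf.oob_error(model, data) == pytest.approx(0.75)

    def test_oob_error_all_correct_is_zero(self, noisy_separable):
        model = xrf.fit_forest(noisy_separable, Hyperparameters(n_trees=50, seed=8))
        err = xrf.oob_error(model, noisy_separable)
        assert 0.0 <= err <= 1.0

    def test_oob_without_any_oob_sample_rejected(self, separable_dataset):
        trees = [constant_tree(0, 4, [2, 2])]
        model = assemble_model(trees, [[0, 1, 2, 3]], ["a", "b"], n_features=2)
        with pytest.raises(ValueError, match="out-of-bag"):
            xrf.oob_error(model, separable_dataset)


class TestUnseenCategoricalLevel:
    def test_unseen_level_routes_to_majority_child(self):
        # category 0 (3 samples, class a) vs category 1 (1 sample, class b):
        # the left child (== 0) holds the majority, so unseen levels go left.
        X = np.array([[0.0], [0.0], [0.0], [1.0]])
        data = Dataset.from_arrays(X, ["a", "a", "a", "b"], feature_kinds=["categorical"])
        sampler = UniformSampler(1, 1)
        tree = grow_tree([0, 1, 2, 3], data, sampler, n_min=1, tree_seed=0)
        model = assemble_model([tree], [[0, 1, 2, 3]], ["a", "b"])
        model.feature_kinds = ["categorical"]
        model.categories = {"f0": [0.0, 1.0]}
        preds = xrf.predict(model, np.array([[-1.0]]))  # -1 = unseen level code
        assert preds.tolist() == ["a"]
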