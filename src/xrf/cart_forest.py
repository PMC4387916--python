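"""CART tree induction with gini splitting, bagging, voting, and OOB error.

The forest substrate is sampler-agnostic: any object satisfying the
subspace-sampler contract (callable ``(available_features, node_rng) ->
candidate index array``) can be injected at the nodes.  The stratified
strong/weak sampler lives in :mod:`xrf.feature_partition`; the plain
uniform sampler is here.

Two growers produce identical trees: a pure-Python reference (handles
categorical features, accepts arbitrary samplers) and a numba kernel for
all-numeric tables with the built-in samplers (see :mod:`xrf._kernel`).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Union

import numpy as np

from ._rng import NodeRng, partial_fisher_yates
from .data_model import (
    CATEGORICAL,
    Dataset,
    ForestModel,
    Hyperparameters,
    Tree,
    default_mtry,
)

__all__ = [
    "gini_impurity",
    "gini_split",
    "best_split",
    "grow_tree",
    "fit_forest",
    "predict",
    "vote_matrix",
    "oob_error",
    "UniformSampler",
]


# ---------------------------------------------------------------------------
# Impurity


def gini_impurity(class_counts: Sequence[int]) -> float:
    """Gini index 1 - sum_j p_j^2 of a node's class counts."""
    counts = np.asarray(class_counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("class counts must be nonnegative")
    total = int(counts.sum())
    if total < 1:
        raise ValueError("node must contain at least one sample")
    ss = 0.0
    for c in counts.tolist():  # sequential sum, matches the compiled kernel
        ss += c * c
    return 1.0 - ss / (total * total)


def gini_split(parent_counts, left_counts, right_counts) -> float:
    """Sample-weighted child impurity (N1/N) gini(left) + (N2/N) gini(right)."""
    p = np.asarray(parent_counts, dtype=np.int64)
    l = np.asarray(left_counts, dtype=np.int64)
    r = np.asarray(right_counts, dtype=np.int64)
    if not np.array_equal(l + r, p):
        raise ValueError("left + right must equal parent counts")
    nl, nr = int(l.sum()), int(r.sum())
    if nl == 0 or nr == 0:
        raise ValueError("both children must be nonempty")
    n = nl + nr
    return (nl * gini_impurity(l) + nr * gini_impurity(r)) / n


# ---------------------------------------------------------------------------
# Split search (reference implementation)


def best_split(rows, candidates, data: Dataset):
    """Exhaustive best split over ``candidates`` at the node holding ``rows``.

    Numeric features: every midpoint between consecutive distinct sorted
    values.  Categorical features: one-category-versus-rest.  Returns
    ``(feature, split_point, gini_split_value)`` minimizing the weighted
    child gini, or ``None`` when no admissible cut exists.  Ties: lowest
    feature index, then smallest cut (strict-less scan order).
    """
    rows = np.asarray(rows, dtype=np.int64)
    if len(candidates) == 0:
        raise ValueError("candidate set must be nonempty")
    n_t = rows.shape[0]
    y = data.y[rows]
    n_classes = data.n_classes
    cnt = np.bincount(y, minlength=n_classes).astype(np.int64)

    best_g = math.inf
    best = None
    for f in sorted(int(c) for c in set(candidates)):
        v = data.X[rows, f]
        if data.feature_kinds[f] == CATEGORICAL:
            for code in np.unique(v):
                mask = v == code
                nl = int(mask.sum())
                if nl == 0 or nl == n_t:
                    continue
                cl = np.bincount(y[mask], minlength=n_classes).astype(np.int64)
                g = _weighted_child_gini(cnt, cl, nl, n_t, n_classes)
                if g < best_g:
                    best_g = g
                    best = (f, float(code), g)
        else:
            order = np.argsort(v)
            cl = np.zeros(n_classes, dtype=np.int64)
            for i in range(n_t - 1):
                cl[y[order[i]]] += 1
                v0 = v[order[i]]
                v1 = v[order[i + 1]]
                if v0 < v1:
                    nl = i + 1
                    g = _weighted_child_gini(cnt, cl, nl, n_t, n_classes)
                    if g < best_g:
                        best_g = g
                        thr = 0.5 * (v0 + v1)
                        if thr >= v1:
                            thr = v0
                        best = (f, float(thr), g)
    return best


def _weighted_child_gini(cnt, cl, nl, n_t, n_classes) -> float:
    # same arithmetic (and accumulation order) as the compiled kernel
    nr = n_t - nl
    ssl = 0.0
    ssr = 0.0
    for j in range(n_classes):
        c = int(cl[j])
        ssl += c * c
        cr = int(cnt[j]) - c
        ssr += cr * cr
    gl = 1.0 - ssl / (nl * nl)
    gr = 1.0 - ssr / (nr * nr)
    return (nl * gl + nr * gr) / n_t


# ---------------------------------------------------------------------------
# Subspace samplers


class UniformSampler:
    """Plain random-forest sampler: mtry features uniformly without replacement."""

    def __init__(self, mtry: int, n_features: int) -> None:
        if not (1 <= mtry <= n_features):
            raise ValueError("mtry must satisfy 1 <= mtry <= n_features")
        self.mtry = mtry
        # fast-path contract consumed by the compiled kernel
        self.strong_group = np.arange(n_features, dtype=np.int64)
        self.weak_group = np.empty(0, dtype=np.int64)
        self.k_strong = mtry
        self.k_weak = 0

    def __call__(self, available: np.ndarray, node_rng: NodeRng) -> np.ndarray:
        drawn = partial_fisher_yates(self.strong_group.tolist(), self.k_strong, node_rng)
        return np.sort(np.asarray(drawn, dtype=np.int64))


# ---------------------------------------------------------------------------
# Tree growing (reference implementation)


def grow_tree(bag, data: Dataset, sampler, n_min: int, tree_seed: int) -> Tree:
    """Grow one unpruned CART tree on the bag (pure-Python reference).

    Recursion stops at pure nodes, nodes of size <= ``n_min``, and nodes
    with no admissible split.  Leaves predict the in-bag majority class
    (ties to the smallest class index).  Node ids are pre-order; the
    subspace draw at node ``i`` uses ``NodeRng(tree_seed, i)``.
    """
    bag = np.asarray(bag, dtype=np.int64)
    if bag.size == 0:
        raise ValueError("bag must be nonempty")
    n_classes = data.n_classes
    all_features = np.arange(data.n_features, dtype=np.int64)

    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    leaf_class: list[int] = []
    n_node: list[int] = []
    impurity: list[float] = []
    counts: list[np.ndarray] = []

    def rec(rows: np.ndarray) -> int:
        node = len(feature)
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        leaf_class.append(-1)
        n_t = rows.shape[0]
        cnt = np.bincount(data.y[rows], minlength=n_classes).astype(np.int64)
        impur = gini_impurity(cnt)
        n_node.append(n_t)
        impurity.append(impur)
        counts.append(cnt)

        split = None
        if impur > 0.0 and n_t > n_min:
            node_rng = NodeRng(tree_seed, node)
            cand = sampler(all_features, node_rng)
            split = best_split(rows, cand, data)
        if split is None:
            leaf_class[node] = int(np.argmax(cnt))
            return node

        f, point, _ = split
        feature[node] = f
        threshold[node] = point
        v = data.X[rows, f]
        if data.feature_kinds[f] == CATEGORICAL:
            mask = v == point
        else:
            mask = v <= point
        left[node] = rec(rows[mask])
        right[node] = rec(rows[~mask])
        return node

    rec(bag)
    cc = np.vstack(counts)
    return Tree(feature, threshold, left, right, leaf_class, n_node, impurity, cc)


def _grow_tree_compiled(bag, data: Dataset, sampler, n_min: int, tree_seed: int) -> Tree:
    from ._kernel import grow_tree_numeric

    out = grow_tree_numeric(
        data.X,
        data.y,
        data.n_classes,
        np.asarray(bag, dtype=np.int64),
        sampler.strong_group,
        sampler.weak_group,
        sampler.k_strong,
        sampler.k_weak,
        n_min,
        np.uint64(tree_seed & ((1 << 64) - 1)),
    )
    return Tree(*out)


def _has_fast_path(data: Dataset, sampler) -> bool:
    if any(k == CATEGORICAL for k in data.feature_kinds):
        return False
    return all(
        hasattr(sampler, a) for a in ("strong_group", "weak_group", "k_strong", "k_weak")
    )


# ---------------------------------------------------------------------------
# Forest fitting


def fit_forest(
    data: Dataset,
    hyper: Hyperparameters,
    sampler=None,
    *,
    random_state: Optional[np.random.SeedSequence] = None,
    partition=None,
    engine: str = "auto",
) -> ForestModel:
    """Fit K trees, each on an independent size-N bootstrap bag.

    ``random_state`` (a ``SeedSequence``) overrides ``hyper.seed`` so a
    caller can hand the forest its own stream.  ``engine``: ``"auto"``
    picks the compiled grower when the table is all-numeric and the
    sampler is one of the built-ins, ``"python"``/``"compiled"`` force a
    path (the two are bit-identical; forcing exists for tests).
    """
    if data.y is None:
        raise ValueError("training data must carry labels")
    n, M = data.n_samples, data.n_features
    mtry = hyper.mtry if hyper.mtry is not None else default_mtry(M, hyper.mtry_rule)
    mtry = min(mtry, M)
    if sampler is None:
        sampler = UniformSampler(mtry, M)

    ss = random_state if random_state is not None else np.random.SeedSequence(hyper.seed)
    children = ss.spawn(hyper.n_trees)

    fast = _has_fast_path(data, sampler)
    if engine == "compiled" and not fast:
        raise ValueError("compiled engine requires an all-numeric table and a built-in sampler")
    use_fast = fast and engine != "python"

    trees: list[Tree] = []
    bags: list[np.ndarray] = []
    for child in children:
        state = child.generate_state(4, dtype=np.uint64)
        tree_seed = int(state[0])
        bag_rng = np.random.default_rng(state[1:])
        bag = bag_rng.integers(0, n, size=n, dtype=np.int64)
        if use_fast:
            tree = _grow_tree_compiled(bag, data, sampler, hyper.n_min, tree_seed)
        else:
            tree = grow_tree(bag, data, sampler, hyper.n_min, tree_seed)
        trees.append(tree)
        bags.append(bag)

    return ForestModel(
        trees=trees,
        bag_indices=bags,
        partition=partition,
        hyper=hyper,
        class_labels=list(data.class_labels),
        feature_names=list(data.feature_names),
        feature_kinds=list(data.feature_kinds),
        categories=dict(data.categories),
        rng_seed=hyper.seed,
    )


# ---------------------------------------------------------------------------
# Prediction


def _encode_for_model(model: ForestModel, data: Union[Dataset, np.ndarray]) -> np.ndarray:
    if isinstance(data, np.ndarray):
        X = np.asarray(data, dtype=np.float64)
        if X.shape[1] != len(model.feature_names):
            raise ValueError("column count does not match the training schema")
        return X
    if data.feature_names != model.feature_names:
        raise ValueError("feature columns do not match the training schema")
    X = data.X.copy()
    for j, name in enumerate(model.feature_names):
        if model.feature_kinds[j] == CATEGORICAL:
            own = data.categories.get(name)
            ref = {v: i for i, v in enumerate(model.categories[name])}
            if own is None:  # already coded against the model's levels
                continue
            X[:, j] = [ref.get(own[int(c)], -1) for c in data.X[:, j]]
    return X


def _tree_predict(tree: Tree, X: np.ndarray, is_cat: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    out = np.empty(n, dtype=np.int64)
    stack = [(0, np.arange(n, dtype=np.int64))]
    while stack:
        nid, rows = stack.pop()
        f = tree.feature[nid]
        if f < 0:
            out[rows] = tree.leaf_class[nid]
            continue
        v = X[rows, f]
        if is_cat[f]:
            go_left = v == tree.threshold[nid]
            unseen = v < 0
            if unseen.any():
                # unseen level: follow the child holding the majority of
                # the node's training samples (left on ties)
                l, r = tree.left[nid], tree.right[nid]
                if tree.n_node[l] >= tree.n_node[r]:
                    go_left = go_left | unseen
        else:
            go_left = v <= tree.threshold[nid]
        lrows = rows[go_left]
        rrows = rows[~go_left]
        if lrows.size:
            stack.append((int(tree.left[nid]), lrows))
        if rrows.size:
            stack.append((int(tree.right[nid]), rrows))
    return out


def vote_matrix(
    model: ForestModel,
    data: Union[Dataset, np.ndarray],
    oob_only: bool = False,
    normalize: bool = False,
) -> np.ndarray:
    """(N, c) tree-vote counts; with ``oob_only`` only out-of-bag trees count.

    ``oob_only`` is meaningful only for the training table (bags index
    into it); rows that are in-bag for every tree get an all-zero row.
    """
    X = _encode_for_model(model, data)
    n = X.shape[0]
    c = model.n_classes
    is_cat = np.array([k == CATEGORICAL for k in model.feature_kinds])
    votes = np.zeros((n, c), dtype=np.int64)
    rows = np.arange(n)
    if oob_only:
        masks = model.oob_masks(n)
    for k, tree in enumerate(model.trees):
        preds = _tree_predict(tree, X, is_cat)
        if oob_only:
            sel = masks[k]
            np.add.at(votes, (rows[sel], preds[sel]), 1)
        else:
            np.add.at(votes, (rows, preds), 1)
    if normalize:
        totals = votes.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, votes / totals, 0.0)
    return votes


def predict(model: ForestModel, data: Union[Dataset, np.ndarray]) -> np.ndarray:
    """Majority-vote class labels (vote ties go to the smallest class label)."""
    votes = vote_matrix(model, data)
    codes = np.argmax(votes, axis=1)
    return np.asarray(model.class_labels, dtype=object)[codes]


def predict_codes(model: ForestModel, data: Union[Dataset, np.ndarray]) -> np.ndarray:
    votes = vote_matrix(model, data)
    return np.argmax(votes, axis=1)


def oob_error(model: ForestModel, data: Dataset) -> float:
    """Misclassification rate of OOB majority votes.

    Samples that are in-bag for every tree have no OOB vote and are
    excluded from the denominator; it is an error if no sample has one.
    """
    if data.y is None:
        raise ValueError("OOB error needs the labeled training table")
    votes = vote_matrix(model, data, oob_only=True)
    has_vote = votes.sum(axis=1) > 0
    if not has_vote.any():
        raise ValueError("no sample is out-of-bag for any tree")
    preds = np.argmax(votes[has_vote], axis=1)
    return float(np.mean(preds != data.y[has_vote]))
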