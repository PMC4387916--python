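"""Feature-importance measures.

In-bag (mean-decrease-impurity) importance: each internal node splitting
on feature j contributes the impurity decrease R(t) - Gini_split(t),
weighted by the fraction of the bag reaching the node; per-forest scores
average the per-tree sums.  The node-fraction weighting keeps the
conservation identity (sum of scores = total weighted impurity decrease)
and is the standard CART convention; ``weighted=False`` gives the literal
unweighted sum of decreases.

OOB permutation importance: the increase in a tree's out-of-bag error
after shuffling one column, averaged over trees.
"""

from __future__ import annotations

import numpy as np

from .data_model import CATEGORICAL, Dataset, ForestModel, Tree
from .cart_forest import _tree_predict

__all__ = ["tree_importance", "forest_importance", "oob_permutation_importance"]


def tree_importance(
    tree: Tree, n_total: int, n_features: int, weighted: bool = True
) -> np.ndarray:
    """Per-feature impurity-decrease scores of one tree (>= 0; unused -> 0)."""
    vec = np.zeros(n_features, dtype=np.float64)
    internal = np.flatnonzero(tree.feature >= 0)
    if internal.size == 0:
        return vec
    l = tree.left[internal]
    r = tree.right[internal]
    n_t = tree.n_node[internal].astype(np.float64)
    g_split = (tree.n_node[l] * tree.impurity[l] + tree.n_node[r] * tree.impurity[r]) / n_t
    delta = tree.impurity[internal] - g_split
    if weighted:
        delta = delta * (n_t / float(n_total))
    np.add.at(vec, tree.feature[internal], delta)
    return vec


def forest_importance(model: ForestModel, weighted: bool = True) -> np.ndarray:
    """(1/K) sum of per-tree scores over all K trees."""
    M = len(model.feature_names)
    vec = np.zeros(M, dtype=np.float64)
    for tree, bag in zip(model.trees, model.bag_indices):
        vec += tree_importance(tree, bag.shape[0], M, weighted=weighted)
    return vec / len(model.trees)


def oob_permutation_importance(
    model: ForestModel,
    data: Dataset,
    rng: np.random.Generator,
    n_repeats: int = 1,
) -> np.ndarray:
    """Mean OOB error increase per feature after permuting its column.

    For each tree only features that actually appear in its splits are
    permuted (any other column leaves the tree's predictions unchanged,
    so its contribution is exactly zero).  Scores are averaged over all
    K trees and, optionally, over ``n_repeats`` fresh permutations.
    """
    if data.y is None:
        raise ValueError("permutation importance needs the labeled training table")
    M = data.n_features
    is_cat = np.array([k == CATEGORICAL for k in data.feature_kinds])
    vec = np.zeros(M, dtype=np.float64)
    masks = model.oob_masks(data.n_samples)
    for k, tree in enumerate(model.trees):
        oob = np.flatnonzero(masks[k])
        if oob.size == 0:
            continue
        X_oob = np.ascontiguousarray(data.X[oob])
        y_oob = data.y[oob]
        base_err = np.mean(_tree_predict(tree, X_oob, is_cat) != y_oob)
        for f in tree.used_features():
            acc = 0.0
            for _ in range(n_repeats):
                X_perm = X_oob.copy()
                X_perm[:, f] = X_oob[rng.permutation(oob.size), f]
                perm_err = np.mean(_tree_predict(tree, X_perm, is_cat) != y_oob)
                acc += perm_err - base_err
            vec[f] += acc / n_repeats
    return vec / len(model.trees)
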