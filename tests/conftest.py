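import numpy as np
import pytest

from xrf import Dataset, ForestModel, Hyperparameters, Tree


@pytest.fixture
def separable_dataset():
    """Four samples, one perfectly separating numeric feature plus a dud."""
    X = np.array([[1.0, 7.0], [2.0, 7.0], [9.0, 7.0], [10.0, 7.0]])
    return Dataset.from_arrays(X, ["a", "a", "b", "b"])


@pytest.fixture
def noisy_separable():
    """Sixty samples: two informative columns, a handful of noise columns."""
    rng = np.random.default_rng(42)
    n = 60
    y = np.arange(n) % 2
    X = rng.standard_normal((n, 6))
    X[:, 0] += y * 3.0
    X[:, 1] -= y * 3.0
    return Dataset.from_arrays(X, y)


def constant_tree(leaf_class: int, n: int, counts) -> Tree:
    """Single-leaf tree that predicts ``leaf_class`` everywhere."""
    counts = np.asarray(counts, dtype=np.int64)
    total = counts.sum()
    imp = 1.0 - float((counts.astype(float) ** 2).sum()) / (total * total)
    return Tree([-1], [0.0], [-1], [-1], [leaf_class], [n], [imp], counts[None, :])


def assemble_model(trees, bags, class_labels, n_features=1) -> ForestModel:
    """Hand-built forest over numeric features f0..f{M-1}."""
    return ForestModel(
        trees=list(trees),
        bag_indices=[np.asarray(b, dtype=np.int64) for b in bags],
        partition=None,
        hyper=Hyperparameters(n_trees=len(trees), seed=0),
        class_labels=list(class_labels),
        feature_names=[f"f{j}" for j in range(n_features)],
        feature_kinds=["numeric"] * n_features,
        categories={},
        rng_seed=0,
    )
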