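"""Domain types shared by every module, plus CSV loading and model (de)serialization.

The in-memory convention: the feature table is a dense ``float64`` matrix
``X`` (Fortran order, columns are accessed far more often than rows);
categorical features are stored as integer category codes with the
code -> level mapping kept in :attr:`Dataset.categories` so files round-trip.
Class labels are stored as integer codes into the sorted ``class_labels``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

NUMERIC = "numeric"
CATEGORICAL = "categorical"

_MODEL_MAGIC = "xrf-model"
_MODEL_VERSION = 1


class DataError(ValueError):
    """Raised for malformed input tables."""


class ModelFormatError(ValueError):
    """Raised when a serialized model is missing, corrupt, or from another version."""


# ---------------------------------------------------------------------------
# Dataset


@dataclass
class Dataset:
    """A classification table: N samples x M features plus a class column.

    ``X``             (N, M) float64; categorical columns hold category codes.
    ``y``             (N,) int codes into ``class_labels`` (None for
                      unlabeled prediction tables).
    ``feature_kinds`` per-feature flag, ``"numeric"`` or ``"categorical"``.
    ``categories``    feature name -> list of levels (index = code).
    """

    X: np.ndarray
    y: Optional[np.ndarray]
    feature_names: list[str]
    feature_kinds: list[str]
    class_labels: list[Any]
    categories: dict[str, list[Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asfortranarray(np.asarray(self.X, dtype=np.float64))
        if self.X.ndim != 2:
            raise DataError("feature matrix must be 2-dimensional")
        n, m = self.X.shape
        if m < 1:
            raise DataError("need at least one feature")
        if len(self.feature_names) != m or len(self.feature_kinds) != m:
            raise DataError("feature metadata length mismatch")
        if np.isnan(self.X).any():
            raise DataError("missing values unsupported")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=np.int64)
            if self.y.shape != (n,):
                raise DataError("label vector length mismatch")
            if n < 2:
                raise DataError("need at least two samples")
            if len(self.class_labels) < 2:
                raise DataError("need at least two classes")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def labels(self) -> np.ndarray:
        """Decoded class labels (original values)."""
        if self.y is None:
            raise DataError("dataset carries no labels")
        return np.asarray(self.class_labels, dtype=object)[self.y]

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        cols: dict[str, Any] = {}
        for j, name in enumerate(self.feature_names):
            col = self.X[:, j]
            if self.feature_kinds[j] == CATEGORICAL:
                levels = self.categories[name]
                cols[name] = [levels[int(c)] for c in col]
            else:
                cols[name] = col
        df = pd.DataFrame(cols)
        if self.y is not None:
            df[label_column] = self.labels
        return df

    @staticmethod
    def from_arrays(
        X: np.ndarray,
        y: Optional[Sequence],
        feature_names: Optional[Sequence[str]] = None,
        feature_kinds: Optional[Sequence[str]] = None,
    ) -> "Dataset":
        X = np.array(X, dtype=np.float64)  # copy: category coding must not mutate input
        m = X.shape[1]
        names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(m)]
        kinds = list(feature_kinds) if feature_kinds is not None else [NUMERIC] * m
        categories: dict[str, list[Any]] = {}
        for j, kind in enumerate(kinds):
            if kind == CATEGORICAL:
                levels = sorted(set(X[:, j].tolist()))
                code = {v: i for i, v in enumerate(levels)}
                X[:, j] = [code[v] for v in X[:, j]]
                categories[names[j]] = levels
        if y is None:
            return Dataset(X, None, names, kinds, [], categories)
        y_arr = np.asarray(y)
        class_labels = sorted(set(y_arr.tolist()))
        code = {v: i for i, v in enumerate(class_labels)}
        y_codes = np.array([code[v] for v in y_arr], dtype=np.int64)
        return Dataset(X, y_codes, names, kinds, class_labels, categories)

    @staticmethod
    def from_dataframe(
        df: pd.DataFrame,
        label_column: Optional[str],
        feature_kinds: Optional[dict[str, str]] = None,
    ) -> "Dataset":
        if df.isna().any().any():
            raise DataError("missing values unsupported")
        if label_column is not None:
            if label_column not in df.columns:
                raise DataError(f"label column {label_column!r} not found")
            y_raw = df[label_column].tolist()
            feats = df.drop(columns=[label_column])
        else:
            y_raw = None
            feats = df
        names = [str(c) for c in feats.columns]
        if len(names) == 0:
            raise DataError("need at least one feature")
        kinds: list[str] = []
        X = np.empty((len(feats), len(names)), dtype=np.float64)
        categories: dict[str, list[Any]] = {}
        for j, col in enumerate(feats.columns):
            override = None if feature_kinds is None else feature_kinds.get(str(col))
            series = feats[col]
            numeric = pd.api.types.is_numeric_dtype(series)
            kind = override or (NUMERIC if numeric else CATEGORICAL)
            kinds.append(kind)
            if kind == NUMERIC:
                X[:, j] = pd.to_numeric(series).to_numpy(dtype=np.float64)
            else:
                levels = sorted(set(series.tolist()), key=repr)
                code = {v: i for i, v in enumerate(levels)}
                X[:, j] = [code[v] for v in series.tolist()]
                categories[names[j]] = levels
        if y_raw is None:
            return Dataset(X, None, names, kinds, [], categories)
        class_labels = sorted(set(y_raw), key=repr)
        if len(class_labels) < 2:
            raise DataError("label column must contain at least two classes")
        code = {v: i for i, v in enumerate(class_labels)}
        y = np.array([code[v] for v in y_raw], dtype=np.int64)
        return Dataset(X, y, names, kinds, class_labels, categories)

    def encode_like(self, other: "Dataset") -> "Dataset":
        """Re-encode this table against ``other``'s schema (training data).

        Feature names must match in order.  Unseen categorical levels map
        to code -1 (routed at prediction time to the majority child).
        """
        if self.feature_names != other.feature_names:
            raise DataError("feature columns do not match the training schema")
        X = self.X.copy()
        for j, name in enumerate(other.feature_names):
            if other.feature_kinds[j] == CATEGORICAL:
                own_levels = self.categories.get(name, [])
                ref = {v: i for i, v in enumerate(other.categories[name])}
                col = np.array(
                    [ref.get(own_levels[int(c)], -1) for c in self.X[:, j]],
                    dtype=np.float64,
                )
                X[:, j] = col
        y = None
        if self.y is not None:
            ref_cls = {v: i for i, v in enumerate(other.class_labels)}
            try:
                y = np.array([ref_cls[v] for v in self.labels], dtype=np.int64)
            except KeyError as exc:  # pragma: no cover - defensive
                raise DataError(f"unseen class label {exc.args[0]!r}") from exc
        return Dataset(
            X, y, list(other.feature_names), list(other.feature_kinds),
            list(other.class_labels), dict(other.categories),
        )


def load_dataset(
    path: str,
    label_column: Optional[str],
    feature_kinds: Optional[dict[str, str]] = None,
) -> Dataset:
    """Read an RFC-4180-style CSV with a header row into a :class:`Dataset`.

    Feature kinds are inferred (numeric when the whole column parses as
    numbers, categorical otherwise) unless overridden per column via
    ``feature_kinds``.  Missing cells and single-class label columns are
    rejected.
    """
    df = pd.read_csv(path)
    return Dataset.from_dataframe(df, label_column, feature_kinds)


# ---------------------------------------------------------------------------
# Hyperparameters


@dataclass
class Hyperparameters:
    """Knobs of the forest and of the screening stage.

    n_trees          K, trees in the final forest (500 by default).
    mtry             candidate features per node; None -> rule below.
    mtry_rule        "sqrt" (ceil(sqrt(M))) or "log2" (ceil(log2(M)+1)).
    n_min            minimum node size; nodes at or below it become leaves.
    n_replicates     R, shadow-importance replicates for the screen.
    replicate_trees  trees per replicate forest during the screen.
    theta            Wilcoxon p-value cut; features with p > theta are dropped.
    chi_alpha        chi-square cut separating strong from weak features.
    n_bins           equal-frequency bins when tabulating numeric features
                     for the chi-square test.
    """

    n_trees: int = 500
    mtry: Optional[int] = None
    mtry_rule: str = "sqrt"
    n_min: int = 1
    n_replicates: int = 30
    replicate_trees: int = 40
    theta: float = 0.05
    chi_alpha: float = 0.05
    n_bins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "n_min", "n_replicates", "replicate_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1 when given")
        for name in ("theta", "chi_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.mtry_rule not in ("sqrt", "log2"):
            raise ValueError("mtry_rule must be 'sqrt' or 'log2'")


# ---------------------------------------------------------------------------
# Trees and forests


class Tree:
    """A fitted CART tree in flat array form (node ids in pre-order)."""

    __slots__ = ("feature", "threshold", "left", "right", "leaf_class",
                 "n_node", "impurity", "class_counts")

    def __init__(self, feature, threshold, left, right, leaf_class,
                 n_node, impurity, class_counts) -> None:
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=np.float64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.leaf_class = np.asarray(leaf_class, dtype=np.int64)
        self.n_node = np.asarray(n_node, dtype=np.int64)
        self.impurity = np.asarray(impurity, dtype=np.float64)
        self.class_counts = np.asarray(class_counts, dtype=np.int64)

    @property
    def node_count(self) -> int:
        return int(self.feature.shape[0])

    @property
    def root(self) -> "TreeNode":
        return TreeNode(self, 0)

    def node(self, i: int) -> "TreeNode":
        return TreeNode(self, i)

    def used_features(self) -> np.ndarray:
        internal = self.feature >= 0
        return np.unique(self.feature[internal])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, s), getattr(other, s))
            for s in Tree.__slots__
        )


class TreeNode:
    """Lightweight view onto one node of a :class:`Tree`.

    Exactly one of (``split_feature`` with two children) or ``leaf_class``
    is set.
    """

    __slots__ = ("_tree", "_i")

    def __init__(self, tree: Tree, i: int) -> None:
        self._tree = tree
        self._i = i

    @property
    def is_leaf(self) -> bool:
        return self._tree.feature[self._i] < 0

    @property
    def split_feature(self) -> Optional[int]:
        f = int(self._tree.feature[self._i])
        return None if f < 0 else f

    @property
    def split_point(self) -> Optional[float]:
        return None if self.is_leaf else float(self._tree.threshold[self._i])

    @property
    def left(self) -> Optional["TreeNode"]:
        return None if self.is_leaf else TreeNode(self._tree, int(self._tree.left[self._i]))

    @property
    def right(self) -> Optional["TreeNode"]:
        return None if self.is_leaf else TreeNode(self._tree, int(self._tree.right[self._i]))

    @property
    def leaf_class(self) -> Optional[int]:
        c = int(self._tree.leaf_class[self._i])
        return None if c < 0 else c

    @property
    def n_samples(self) -> int:
        return int(self._tree.n_node[self._i])

    @property
    def impurity(self) -> float:
        return float(self._tree.impurity[self._i])

    @property
    def class_counts(self) -> np.ndarray:
        return self._tree.class_counts[self._i]


@dataclass
class ForestModel:
    """K bagged CART trees plus everything needed to reproduce them."""

    trees: list[Tree]
    bag_indices: list[np.ndarray]
    partition: Optional[Any]  # FeaturePartition or None (None = plain RF)
    hyper: Hyperparameters
    class_labels: list[Any]
    feature_names: list[str]
    feature_kinds: list[str]
    categories: dict[str, list[Any]]
    rng_seed: int
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def oob_masks(self, n_samples: int) -> np.ndarray:
        """(K, N) boolean: True where sample i is out-of-bag for tree k."""
        masks = np.ones((len(self.trees), n_samples), dtype=bool)
        for k, bag in enumerate(self.bag_indices):
            masks[k, bag] = False
        return masks


# ---------------------------------------------------------------------------
# Serialization (documented JSON; trees as nested objects)


def _node_to_obj(tree: Tree, i: int) -> dict:
    base = {
        "n": int(tree.n_node[i]),
        "counts": [int(c) for c in tree.class_counts[i]],
        "impurity": float(tree.impurity[i]),
    }
    if tree.feature[i] < 0:
        base["leaf_class"] = int(tree.leaf_class[i])
    else:
        base["feature"] = int(tree.feature[i])
        base["threshold"] = float(tree.threshold[i])
        base["left"] = _node_to_obj(tree, int(tree.left[i]))
        base["right"] = _node_to_obj(tree, int(tree.right[i]))
    return base


def _tree_to_obj(tree: Tree) -> dict:
    return _node_to_obj(tree, 0)


def _obj_to_tree(obj: dict, n_classes: int) -> Tree:
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    leaf_class: list[int] = []
    n_node: list[int] = []
    impurity: list[float] = []
    counts: list[list[int]] = []

    def rec(node: dict) -> int:
        i = len(feature)
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        leaf_class.append(-1)
        n_node.append(int(node["n"]))
        impurity.append(float(node["impurity"]))
        counts.append([int(c) for c in node["counts"]])
        if "feature" in node:
            feature[i] = int(node["feature"])
            threshold[i] = float(node["threshold"])
            left[i] = rec(node["left"])
            right[i] = rec(node["right"])
        else:
            leaf_class[i] = int(node["leaf_class"])
        return i

    rec(obj)
    cc = np.asarray(counts, dtype=np.int64).reshape(len(feature), n_classes)
    return Tree(feature, threshold, left, right, leaf_class, n_node, impurity, cc)


def _partition_to_obj(partition: Any) -> Optional[dict]:
    if partition is None:
        return None
    return {
        "informative": [int(j) for j in partition.informative],
        "strong": [int(j) for j in partition.strong],
        "weak": [int(j) for j in partition.weak],
        "discarded": [int(j) for j in partition.discarded],
        "wilcoxon_p": [float(p) for p in partition.wilcoxon_p],
        "chi2_stat": {str(k): float(v) for k, v in partition.chi2_stat.items()},
        "chi2_p": {str(k): float(v) for k, v in partition.chi2_p.items()},
        "theta": float(partition.theta),
        "chi_alpha": float(partition.chi_alpha),
    }


def _obj_to_partition(obj: Optional[dict]) -> Optional[Any]:
    if obj is None:
        return None
    from .feature_partition import FeaturePartition

    return FeaturePartition(
        informative=np.asarray(obj["informative"], dtype=np.int64),
        strong=np.asarray(obj["strong"], dtype=np.int64),
        weak=np.asarray(obj["weak"], dtype=np.int64),
        discarded=np.asarray(obj["discarded"], dtype=np.int64),
        wilcoxon_p=np.asarray(obj["wilcoxon_p"], dtype=np.float64),
        chi2_stat={int(k): v for k, v in obj["chi2_stat"].items()},
        chi2_p={int(k): v for k, v in obj["chi2_p"].items()},
        theta=obj["theta"],
        chi_alpha=obj["chi_alpha"],
    )


def save_model(model: ForestModel, path: str) -> None:
    """Write a forest as documented, diffable JSON."""
    from dataclasses import asdict

    obj = {
        "format": _MODEL_MAGIC,
        "version": _MODEL_VERSION,
        "class_labels": model.class_labels,
        "feature_names": model.feature_names,
        "feature_kinds": model.feature_kinds,
        "categories": model.categories,
        "hyper": asdict(model.hyper),
        "rng_seed": int(model.rng_seed),
        "provenance": model.provenance,
        "bag_indices": [[int(i) for i in bag] for bag in model.bag_indices],
        "partition": _partition_to_obj(model.partition),
        "trees": [_tree_to_obj(t) for t in model.trees],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, separators=(",", ":"))


def load_model(path: str) -> ForestModel:
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except FileNotFoundError:
        raise
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"corrupt model file: {exc}") from exc
    if not isinstance(obj, dict) or obj.get("format") != _MODEL_MAGIC:
        raise ModelFormatError("corrupt model: bad magic header")
    if obj.get("version") != _MODEL_VERSION:
        raise ModelFormatError(
            f"model version mismatch: file has {obj.get('version')}, "
            f"reader supports {_MODEL_VERSION}"
        )
    n_classes = len(obj["class_labels"])
    return ForestModel(
        trees=[_obj_to_tree(t, n_classes) for t in obj["trees"]],
        bag_indices=[np.asarray(b, dtype=np.int64) for b in obj["bag_indices"]],
        partition=_obj_to_partition(obj["partition"]),
        hyper=Hyperparameters(**obj["hyper"]),
        class_labels=obj["class_labels"],
        feature_names=obj["feature_names"],
        feature_kinds=obj["feature_kinds"],
        categories={k: list(v) for k, v in obj["categories"].items()},
        rng_seed=int(obj["rng_seed"]),
        provenance=obj.get("provenance", {}),
    )


def default_mtry(M: int, rule: str = "sqrt") -> int:
    """Subspace-size rules: ``sqrt`` -> ceil(sqrt(M)); ``log2`` -> ceil(log2(M)+1)."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if rule == "sqrt":
        return int(math.ceil(math.sqrt(M)))
    if rule == "log2":
        return int(math.ceil(math.log2(M) + 1.0))
    raise ValueError("rule must be 'sqrt' or 'log2'")
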