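"""Shadow-feature screening: replicate importances and rank-sum p-values.

Every real feature X_j gets a shadow A_j — an independent random
permutation of its column.  A shadow keeps the marginal distribution,
the possible cut points, and (for categorical features) the cardinality
of its source, but carries no association with the class, so it is an
honest null for the importance measure *at the same measurement level*.
This is what debiases the screen against the multivalue problem: a
high-cardinality feature is compared against an equally high-cardinality
shadow.

The screen fits R replicate forests on the 2M-column extended table
(fresh shadow permutations each replicate), collects in-bag importance
scores, and tests each feature's R scores against the R per-replicate
*maxima* over all shadows with a one-sided Wilcoxon rank-sum test.
Comparing against the max makes the screen conservative: a feature must
consistently beat the luckiest of M nulls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import Dataset, ForestModel, Hyperparameters
from .cart_forest import fit_forest
from .importance import forest_importance

__all__ = [
    "SHADOW_SUFFIX",
    "ImportanceReplicates",
    "FeatureWeights",
    "make_shadow",
    "importance_replicates",
    "feature_pvalues",
]

SHADOW_SUFFIX = "__shadow"


@dataclass
class ImportanceReplicates:
    """R x M in-bag importance scores of real features and their shadows."""

    is_x: np.ndarray      # (R, M) real-feature scores
    is_a: np.ndarray      # (R, M) shadow scores
    is_a_max: np.ndarray  # (R,) rowwise max over shadows

    def __post_init__(self) -> None:
        self.is_x = np.asarray(self.is_x, dtype=np.float64)
        self.is_a = np.asarray(self.is_a, dtype=np.float64)
        self.is_a_max = np.asarray(self.is_a_max, dtype=np.float64)
        if self.is_x.shape != self.is_a.shape:
            raise ValueError("real and shadow score matrices must share a shape")
        if not np.allclose(self.is_a_max, self.is_a.max(axis=1)):
            raise ValueError("is_a_max must be the rowwise maximum of is_a")

    @property
    def n_replicates(self) -> int:
        return self.is_x.shape[0]

    @property
    def n_features(self) -> int:
        return self.is_x.shape[1]


@dataclass
class FeatureWeights:
    """Per-feature one-sided rank-sum p-values (small = informative)."""

    p_values: np.ndarray
    mean_importance: np.ndarray
    replicates: ImportanceReplicates


def make_shadow(data: Dataset, rng: np.random.Generator) -> Dataset:
    """Extend the table to 2M columns by appending one shadow per feature.

    Shadow A_j is an independent uniform random permutation of column j;
    labels are untouched.  Shadow columns are named ``<name>__shadow``
    and keep their source's kind (and category map).
    """
    n, m = data.X.shape
    X_ext = np.empty((n, 2 * m), dtype=np.float64)
    X_ext[:, :m] = data.X
    for j in range(m):
        X_ext[:, m + j] = data.X[rng.permutation(n), j]
    names = list(data.feature_names) + [f"{nm}{SHADOW_SUFFIX}" for nm in data.feature_names]
    kinds = list(data.feature_kinds) * 2
    categories = dict(data.categories)
    for nm in data.feature_names:
        if nm in data.categories:
            categories[f"{nm}{SHADOW_SUFFIX}"] = list(data.categories[nm])
    return Dataset(X_ext, data.y, names, kinds, list(data.class_labels), categories)


def importance_replicates(
    data: Dataset,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> ImportanceReplicates:
    """R replicate forests on freshly shadowed data -> importance matrices.

    Each replicate regenerates all M shadows, fits a plain forest of
    ``hyper.replicate_trees`` trees with mtry = ceil(sqrt(2M)) on the
    extended table, and records the forest's in-bag importance of all
    2M columns.

    The 2M columns are presented to each replicate forest in a fresh
    random order (importances are mapped back afterwards).  Split-value
    ties are broken by column index, so a fixed real-then-shadow layout
    would hand every tied contest to a real feature — a systematic edge
    that matters on low-cardinality tables where exact gini ties are
    common.  Shuffling restores the real/shadow exchangeability the null
    comparison relies on.
    """
    if hyper.n_replicates < 2:
        raise ValueError("need at least two replicates for a rank-sum comparison")
    m = data.n_features
    rep_hyper = Hyperparameters(
        n_trees=hyper.replicate_trees,
        mtry=int(math.ceil(math.sqrt(2 * m))),
        n_min=hyper.n_min,
        seed=hyper.seed,
    )
    is_x = np.empty((hyper.n_replicates, m), dtype=np.float64)
    is_a = np.empty((hyper.n_replicates, m), dtype=np.float64)
    for r in range(hyper.n_replicates):
        extended = make_shadow(data, rng)
        order = rng.permutation(2 * m)
        shuffled = Dataset(
            extended.X[:, order],
            extended.y,
            [extended.feature_names[j] for j in order],
            [extended.feature_kinds[j] for j in order],
            list(extended.class_labels),
            dict(extended.categories),
        )
        forest_seed = np.random.SeedSequence(int(rng.integers(0, 2**31)))
        model = fit_forest(shuffled, rep_hyper, random_state=forest_seed)
        imp_shuffled = forest_importance(model)
        imp = np.empty(2 * m, dtype=np.float64)
        imp[order] = imp_shuffled
        is_x[r] = imp[:m]
        is_a[r] = imp[m:]
    return ImportanceReplicates(is_x, is_a, is_a.max(axis=1))


def _rank_sum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p-value for H1: x stochastically > y.

    Exact enumeration when both samples are small (n <= 12) and tie-free;
    otherwise the normal approximation with tie and continuity
    corrections.  Degenerate all-tied samples return 1.0 (zero rank-sum
    variance carries no evidence of separation).
    """
    combined = np.concatenate([x, y])
    if combined.max() == combined.min():
        return 1.0
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (no_ties and len(x) <= 12 and len(y) <= 12) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    p = float(res.pvalue)
    if math.isnan(p):  # zero variance under heavy ties
        return 1.0
    return p


def feature_pvalues(reps: ImportanceReplicates, bh_adjust: bool = False) -> FeatureWeights:
    """Wilcoxon rank-sum weight of every feature against the max-shadow sample.

    ``bh_adjust`` applies a Benjamini-Hochberg correction across the M
    simultaneous tests before thresholding; the raw per-feature cut is the
    default.
    """
    m = reps.n_features
    p = np.empty(m, dtype=np.float64)
    for j in range(m):
        p[j] = _rank_sum_greater(reps.is_x[:, j], reps.is_a_max)
    if bh_adjust:
        p = stats.false_discovery_control(p, method="bh")
    return FeatureWeights(p, reps.is_x.mean(axis=0), reps)
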