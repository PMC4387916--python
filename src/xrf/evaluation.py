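"""Forest diagnostics: test accuracy, AUC, and Breiman's strength/correlation.

Strength s is the mean out-of-bag margin: with Q(i, j) the OOB vote
fraction for class j on training sample i,

    mr_i = Q(i, y_i) - max_{j != y_i} Q(i, j),        s = mean_i mr_i.

The between-tree correlation rho_bar is estimated from the raw margins:
var(mr) / (mean_k sd_k)^2, where for each tree k (over its OOB samples)
p1_k is the fraction classified correctly, p2_k the fraction classified
as the forest-level most-voted wrong class j_hat(i), and
sd_k = sqrt(p1_k + p2_k + (p1_k - p2_k)^2).  The generalization-error
bound ratio is c/s^2 = rho_bar / s^2 — smaller is better: strong,
decorrelated trees.  The ratio is undefined when s <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .data_model import CATEGORICAL, Dataset, ForestModel
from .cart_forest import _encode_for_model, _tree_predict, oob_error, vote_matrix

__all__ = [
    "EvaluationReport",
    "test_accuracy",
    "auc",
    "strength_correlation",
    "evaluate",
]


@dataclass
class EvaluationReport:
    accuracy: float
    auc: float
    oob_error: float
    strength: float
    correlation: float
    c_over_s2: Optional[float]


def test_accuracy(model: ForestModel, test: Dataset) -> float:
    """Fraction of test samples whose vote margin is strictly positive.

    A tied vote (margin exactly zero) counts as an error.
    """
    if test.y is None:
        raise ValueError("test accuracy needs labeled data")
    votes = vote_matrix(model, test)
    n = votes.shape[0]
    rows = np.arange(n)
    correct = votes[rows, test.y].copy()
    votes_rest = votes.copy()
    votes_rest[rows, test.y] = -1
    margin = correct - votes_rest.max(axis=1)
    return float(np.mean(margin > 0))


def _rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC of scores for the positive class (ties -> 0.5)."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc(model: ForestModel, test: Dataset) -> float:
    """Rank-based AUC of vote fractions; multiclass = macro one-vs-rest.

    Classes absent from the test labels are excluded from the macro
    average.
    """
    if test.y is None:
        raise ValueError("AUC needs labeled data")
    fractions = vote_matrix(model, test, normalize=True)
    present = np.unique(test.y)
    if present.size < model.n_classes:
        import warnings

        warnings.warn(
            "some classes are absent from the test labels and are excluded "
            "from the macro AUC average",
            stacklevel=2,
        )
    aucs = []
    for c in present:
        aucs.append(_rank_auc(fractions[:, c], test.y == c))
    return float(np.mean(aucs))


def strength_correlation(model: ForestModel, train: Dataset):
    """OOB estimates (s, rho_bar, c/s^2) following Breiman's formulas.

    Samples with no OOB tree are skipped; trees with an empty OOB set are
    skipped in the sd average.  Raises when s <= 0 (the bound is
    undefined / unbounded there).
    """
    if train.y is None:
        raise ValueError("strength estimation needs the labeled training table")
    votes = vote_matrix(model, train, oob_only=True)
    totals = votes.sum(axis=1)
    eligible = totals > 0
    if not eligible.any():
        raise ValueError("no sample has an out-of-bag vote")
    q = votes[eligible] / totals[eligible, None]
    y = train.y[eligible]
    rows = np.arange(q.shape[0])

    q_true = q[rows, y]
    q_rest = q.copy()
    q_rest[rows, y] = -np.inf
    j_hat = np.argmax(q_rest, axis=1)  # most-voted wrong class, ties -> smallest
    mr = q_true - q_rest[rows, j_hat]

    s = float(np.mean(mr))
    var_mr = float(np.mean(mr**2) - s**2)

    # map j_hat back to all-sample indexing for the per-tree pass
    j_hat_full = np.zeros(train.n_samples, dtype=np.int64)
    j_hat_full[eligible] = j_hat

    X = _encode_for_model(model, train)
    is_cat = np.array([k == CATEGORICAL for k in model.feature_kinds])
    masks = model.oob_masks(train.n_samples)
    eligible_full = eligible
    sds = []
    for k, tree in enumerate(model.trees):
        oob = np.flatnonzero(masks[k] & eligible_full)
        if oob.size == 0:
            continue
        preds = _tree_predict(tree, np.ascontiguousarray(X[oob]), is_cat)
        p1 = float(np.mean(preds == train.y[oob]))
        p2 = float(np.mean(preds == j_hat_full[oob]))
        sds.append(np.sqrt(p1 + p2 + (p1 - p2) ** 2))
    if not sds:
        raise ValueError("every tree has an empty out-of-bag set")
    sd_mean = float(np.mean(sds))
    rho_bar = var_mr / (sd_mean**2) if sd_mean > 0 else 0.0
    if s <= 0:
        raise ValueError(
            f"strength s = {s:.4f} <= 0: the c/s^2 bound is unbounded for this forest"
        )
    c_over_s2 = rho_bar / (s**2)
    return s, rho_bar, c_over_s2


def evaluate(model: ForestModel, test: Dataset, train: Dataset) -> EvaluationReport:
    """Full report: Acc and AUC on the test table, OOB diagnostics on train."""
    s, rho, c_s2 = strength_correlation(model, train)
    return EvaluationReport(
        accuracy=test_accuracy(model, test),
        auc=auc(model, test),
        oob_error=oob_error(model, train),
        strength=s,
        correlation=rho,
        c_over_s2=c_s2,
    )


def kfold_indices(n_samples: int, n_folds: int, seed: int = 0):
    """Shuffled k-fold (train_idx, test_idx) pairs over ``range(n_samples)``."""
    if not (2 <= n_folds <= n_samples):
        raise ValueError("need 2 <= n_folds <= n_samples")
    order = np.random.default_rng(seed).permutation(n_samples)
    folds = np.array_split(order, n_folds)
    for k in range(n_folds):
        test = np.sort(folds[k])
        train = np.sort(np.concatenate([folds[j] for j in range(n_folds) if j != k]))
        yield train, test
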