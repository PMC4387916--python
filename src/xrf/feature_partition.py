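"""Theta-filtering, chi-square strong/weak partition, and stratified subspaces.

After the shadow screen assigns every feature a rank-sum p-value, features
with p > theta are discarded as uninformative.  Survivors are partitioned
by a chi-square test of association with the class: p <= chi_alpha puts a
feature in the strong group X_s, the rest go to the weak group X_w.  Node
candidate subspaces then draw from both groups in proportion to their
sizes, with a floor of one per nonempty group — so every node sees at
least one strong feature whenever any exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

from ._rng import NodeRng, partial_fisher_yates
from .data_model import CATEGORICAL, Dataset
from .shadow_weighting import FeatureWeights

__all__ = [
    "FeaturePartition",
    "SubspacePlan",
    "filter_informative",
    "chi_square_score",
    "partition_features",
    "subspace_sizes",
    "sample_subspace",
    "PartitionSampler",
]


@dataclass
class FeaturePartition:
    informative: np.ndarray  # X~: survivors of the theta filter
    strong: np.ndarray       # X_s
    weak: np.ndarray         # X_w
    discarded: np.ndarray
    wilcoxon_p: np.ndarray   # length-M, all features
    chi2_stat: dict[int, float] = field(default_factory=dict)
    chi2_p: dict[int, float] = field(default_factory=dict)
    theta: float = 0.05
    chi_alpha: float = 0.05

    def __post_init__(self) -> None:
        self.informative = np.asarray(self.informative, dtype=np.int64)
        self.strong = np.asarray(self.strong, dtype=np.int64)
        self.weak = np.asarray(self.weak, dtype=np.int64)
        self.discarded = np.asarray(self.discarded, dtype=np.int64)
        s, w, inf = set(self.strong), set(self.weak), set(self.informative)
        if s | w != inf or (s & w):
            raise ValueError("strong and weak must partition the informative set")
        if inf & set(self.discarded):
            raise ValueError("informative and discarded sets overlap")


def filter_informative(weights: FeatureWeights, theta: float):
    """Split features at the theta cut: keep p <= theta, discard p > theta."""
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    p = np.asarray(weights.p_values)
    informative = np.flatnonzero(p <= theta).astype(np.int64)
    discarded = np.flatnonzero(p > theta).astype(np.int64)
    return informative, discarded


def chi_square_score(feature_values, labels, n_bins: int = 10, kind: str = "numeric"):
    """Pearson chi-square association of one feature with the class.

    Numeric features are discretized into ``min(n_bins, #distinct)``
    equal-frequency bins before tabulation; categorical features use
    their categories directly.  Rows/columns with zero marginals are
    dropped.  Returns ``(statistic, p_value)`` with df = (r-1)(c-1); a
    table degenerate in either direction scores (0.0, 1.0).
    """
    v = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if v.shape[0] != y.shape[0] or v.shape[0] < 2:
        raise ValueError("need >= 2 samples with matching labels")
    if kind == CATEGORICAL:
        codes = v.astype(np.int64)
    else:
        k = min(n_bins, np.unique(v).size)
        edges = np.unique(np.quantile(v, np.linspace(0.0, 1.0, k + 1)))
        codes = np.searchsorted(edges[1:-1], v, side="right")
    rows = np.unique(codes)
    cols = np.unique(y)
    table = np.zeros((rows.size, cols.size), dtype=np.int64)
    ri = np.searchsorted(rows, codes)
    ci = np.searchsorted(cols, y)
    np.add.at(table, (ri, ci), 1)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def partition_features(
    informative: Iterable[int],
    data: Dataset,
    chi_alpha: float,
    weights: FeatureWeights,
    n_bins: int = 10,
    theta: float = 0.05,
) -> FeaturePartition:
    """Chi-square partition of the informative set into X_s and X_w."""
    informative = np.asarray(sorted(int(j) for j in informative), dtype=np.int64)
    if informative.size == 0:
        raise ValueError("informative set must be nonempty")
    chi2_stat: dict[int, float] = {}
    chi2_p: dict[int, float] = {}
    strong: list[int] = []
    weak: list[int] = []
    for j in informative:
        stat, p = chi_square_score(
            data.X[:, j], data.y, n_bins=n_bins, kind=data.feature_kinds[j]
        )
        chi2_stat[int(j)] = stat
        chi2_p[int(j)] = p
        (strong if p <= chi_alpha else weak).append(int(j))
    all_feats = np.arange(data.n_features, dtype=np.int64)
    discarded = np.setdiff1d(all_feats, informative)
    return FeaturePartition(
        informative=informative,
        strong=np.asarray(strong, dtype=np.int64),
        weak=np.asarray(weak, dtype=np.int64),
        discarded=discarded,
        wilcoxon_p=np.asarray(weights.p_values, dtype=np.float64),
        chi2_stat=chi2_stat,
        chi2_p=chi2_p,
        theta=theta,
        chi_alpha=chi_alpha,
    )


@dataclass(frozen=True)
class SubspacePlan:
    mtry_s: int
    mtry_w: int

    @property
    def mtry(self) -> int:
        return self.mtry_s + self.mtry_w


def subspace_sizes(mtry: int, partition: FeaturePartition) -> SubspacePlan:
    """Proportional allocation mtry_g = mtry * |X_g| / |X~| made integral.

    Largest-remainder rounding keeps the total at ``mtry``; each nonempty
    group receives at least one slot when mtry >= 2; an allocation larger
    than its group is capped with the excess reassigned.
    """
    ns, nw = int(partition.strong.size), int(partition.weak.size)
    ni = ns + nw
    if mtry < 1:
        raise ValueError("mtry must be >= 1")
    if ni == 0:
        raise ValueError("informative set is empty")
    if mtry > ni:
        raise ValueError(f"mtry ({mtry}) exceeds the informative set size ({ni})")
    raw_s = mtry * ns / ni
    raw_w = mtry * nw / ni
    ms, mw = math.floor(raw_s), math.floor(raw_w)
    if ms + mw < mtry:  # one leftover slot -> larger fractional part (strong on ties)
        if (raw_s - ms) >= (raw_w - mw):
            ms += 1
        else:
            mw += 1
    if mtry >= 2:
        if ns > 0 and ms == 0:
            ms, mw = 1, mtry - 1
        elif nw > 0 and mw == 0:
            ms, mw = mtry - 1, 1
    if ms > ns:
        mw += ms - ns
        ms = ns
    if mw > nw:
        ms += mw - nw
        mw = nw
    return SubspacePlan(ms, mw)


def sample_subspace(
    plan: SubspacePlan, partition: FeaturePartition, rng: np.random.Generator
) -> np.ndarray:
    """One candidate subspace: mtry_s strong + mtry_w weak features, merged."""
    if plan.mtry_s > partition.strong.size or plan.mtry_w > partition.weak.size:
        raise ValueError("plan is inconsistent with the partition")
    parts = []
    if plan.mtry_s:
        parts.append(rng.choice(partition.strong, size=plan.mtry_s, replace=False))
    if plan.mtry_w:
        parts.append(rng.choice(partition.weak, size=plan.mtry_w, replace=False))
    return np.sort(np.concatenate(parts).astype(np.int64))


class PartitionSampler:
    """Node-level sampler drawing proportionally from X_s and X_w.

    Satisfies the subspace-sampler contract and exposes the group arrays
    consumed by the compiled grower; the Python ``__call__`` performs the
    identical partial Fisher-Yates draws from the identical per-node
    stream.
    """

    def __init__(self, plan: SubspacePlan, partition: FeaturePartition) -> None:
        if plan.mtry_s > partition.strong.size or plan.mtry_w > partition.weak.size:
            raise ValueError("plan is inconsistent with the partition")
        self.plan = plan
        self.partition = partition
        self.strong_group = np.asarray(partition.strong, dtype=np.int64)
        self.weak_group = np.asarray(partition.weak, dtype=np.int64)
        self.k_strong = plan.mtry_s
        self.k_weak = plan.mtry_w

    def __call__(self, available: np.ndarray, node_rng: NodeRng) -> np.ndarray:
        drawn = partial_fisher_yates(self.strong_group.tolist(), self.k_strong, node_rng)
        drawn += partial_fisher_yates(self.weak_group.tolist(), self.k_weak, node_rng)
        return np.sort(np.asarray(drawn, dtype=np.int64))
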