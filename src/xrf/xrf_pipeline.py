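"""The end-to-end xRF algorithm.

Given a labeled table, the pipeline

1. extends it with shadow features and fits R replicate forests to
   collect in-bag importance scores (shadow screen),
2. converts each feature's R scores into a one-sided Wilcoxon rank-sum
   p-value against the per-replicate max-shadow sample,
3. discards features with p > theta,
4. partitions the survivors into strong/weak groups by chi-square
   association with the class,
5. grows K unpruned CART trees on bootstrap bags, drawing every node's
   candidate subspace proportionally from the two groups.

The screen and the final forest consume disjoint RNG streams spawned
from the master seed, so changing R never silently changes the final
forest's bags.  If the screen discards everything (a pure-noise table),
the pipeline falls back to a plain random forest over all features and
records a warning in the model's provenance.

Also here: the closed-form probability that a simple-random subspace
contains at least one informative feature — the quantity that motivates
stratified subspace sampling in the first place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .data_model import Dataset, ForestModel, Hyperparameters, default_mtry
from .cart_forest import fit_forest
from .shadow_weighting import FeatureWeights, feature_pvalues, importance_replicates
from .feature_partition import (
    FeaturePartition,
    PartitionSampler,
    filter_informative,
    partition_features,
    subspace_sizes,
)

__all__ = ["XrfModel", "fit_xrf", "prob_informative_in_subspace", "default_mtry"]


@dataclass
class XrfModel:
    forest: ForestModel
    weights: FeatureWeights
    partition: Optional[FeaturePartition]
    provenance: dict

    @property
    def used_fallback(self) -> bool:
        return self.partition is None


def fit_xrf(data: Dataset, hyper: Hyperparameters) -> XrfModel:
    """Run the full screen-partition-grow pipeline on a labeled table."""
    if data.y is None:
        raise ValueError("training data must carry labels")
    master = np.random.SeedSequence(hyper.seed)
    ss_screen, ss_forest = master.spawn(2)

    rng_screen = np.random.default_rng(ss_screen)
    reps = importance_replicates(data, hyper, rng_screen)
    weights = feature_pvalues(reps)
    informative, _ = filter_informative(weights, hyper.theta)

    provenance: dict = {
        "seed": hyper.seed,
        "n_informative": int(informative.size),
        "fallback": False,
    }

    if informative.size == 0:
        provenance["fallback"] = True
        provenance["warning"] = (
            "screen discarded every feature; fell back to a plain random "
            "forest over all features"
        )
        forest = fit_forest(data, hyper, sampler=None, random_state=ss_forest)
        forest.provenance.update(provenance)
        return XrfModel(forest, weights, None, provenance)

    partition = partition_features(
        informative, data, hyper.chi_alpha, weights,
        n_bins=hyper.n_bins, theta=hyper.theta,
    )
    mtry = hyper.mtry if hyper.mtry is not None else default_mtry(
        data.n_features, hyper.mtry_rule
    )
    mtry = min(mtry, int(informative.size))  # cannot draw more than survive
    plan = subspace_sizes(mtry, partition)
    sampler = PartitionSampler(plan, partition)
    provenance["n_strong"] = int(partition.strong.size)
    provenance["n_weak"] = int(partition.weak.size)
    provenance["mtry_s"] = plan.mtry_s
    provenance["mtry_w"] = plan.mtry_w
    forest = fit_forest(
        data, hyper, sampler=sampler, random_state=ss_forest, partition=partition
    )
    forest.provenance.update(provenance)
    return XrfModel(forest, weights, partition, provenance)


def prob_informative_in_subspace(
    n_informative: int, n_noise: int, m: int, method: str = "exact"
) -> float:
    """P(a size-m simple-random subspace contains >= 1 informative feature).

    ``exact``: 1 - C(n_noise, m) / C(n_noise + n_informative, m), computed
    with log-factorials.  ``approx``: the geometric-style approximation
    1 - (1 - G/M)^m with G informative among M total features.  With few
    informative features among thousands this probability is tiny — e.g.
    5 informative among 5005 features and m = 70 gives 0.068 — which is
    why uniform subspace sampling starves the trees of signal.
    """
    if n_informative < 0 or n_noise < 0 or m < 0:
        raise ValueError("counts must be nonnegative")
    total = n_informative + n_noise
    if m > total:
        raise ValueError("m cannot exceed the total number of features")
    if n_informative == 0:
        return 0.0
    if m == 0:
        return 0.0
    if method == "exact":
        if m > n_noise:  # pigeonhole: some informative feature must be drawn
            return 1.0
        log_none = (
            _log_comb(n_noise, m) - _log_comb(total, m)
        )
        return 1.0 - math.exp(log_none)
    if method in ("approx", "eq7"):
        return 1.0 - (1.0 - n_informative / total) ** m
    raise ValueError("method must be 'exact' or 'approx'")


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
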