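"""Synthetic benchmark generators.

Three designs capture the data regimes the stratified sampler is meant
to handle:

* ``make_sparse_signal`` — the sparse-signal regime of high-dimensional
  (e.g. microarray) classification: a handful of informative Gaussian
  columns whose class means are separated by ``effect_size`` noise
  standard deviations, buried among label-independent unit-variance
  noise columns.  With balanced classes the analytic Bayes error is
  Phi(-delta * sqrt(G) / 2) for G informative columns at separation
  delta, which calibrates effect sizes.
* ``make_cardinality_null`` — the multivalue-bias *null* case: every
  column is categorical, uniform over its cardinality, and independent
  of the class.  An unbiased learner should not prefer high-cardinality
  columns.
* ``make_cardinality_power`` — the *power* case: one binary column is
  genuinely associated with the class; all other columns are redundant
  categorical noise of varying cardinality.

Each generator is a pure function of its :class:`SimSpec` (the seed is a
spec field) and returns the dataset together with the ground-truth
informative mask, enabling exact precision/recall for the screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .data_model import CATEGORICAL, NUMERIC, Dataset

__all__ = ["SimSpec", "SyntheticData", "make_sparse_signal",
           "make_cardinality_null", "make_cardinality_power"]


@dataclass(frozen=True)
class SimSpec:
    """Design parameters for the generators.

    effect_size: class-mean separation of an informative column, in
    noise-standard-deviation units.  association: for the power design,
    P(X = Y) - 0.5 of the single informative binary column (its levels
    agree with the class 50 + 100a percent of the time).
    """

    n_samples: int = 100
    n_informative: int = 5
    n_noise: int = 500
    n_classes: int = 2
    effect_size: float = 1.5
    cardinalities: Sequence[int] = (2, 4, 10, 20)
    association: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if self.effect_size < 0:
            raise ValueError("effect size must be nonnegative")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not (0.0 <= self.association <= 0.5):
            raise ValueError("association must lie in [0, 0.5]")


class SyntheticData(NamedTuple):
    data: Dataset
    informative_mask: np.ndarray  # boolean, aligned with the dataset's columns


def _balanced_labels(n: int, c: int, rng: np.random.Generator) -> np.ndarray:
    base = np.arange(n) % c
    return base[rng.permutation(n)]


def make_sparse_signal(spec: SimSpec) -> SyntheticData:
    """Few informative Gaussian columns among many noise columns."""
    rng = np.random.default_rng(spec.seed)
    n, g, q = spec.n_samples, spec.n_informative, spec.n_noise
    y = _balanced_labels(n, spec.n_classes, rng)
    m = g + q
    X = rng.standard_normal((n, m))
    # class k is offset by k * delta on every informative column
    X[:, :g] += (y[:, None] * spec.effect_size)
    mask = np.zeros(m, dtype=bool)
    mask[:g] = True
    order = rng.permutation(m)
    X = X[:, order]
    mask = mask[order]
    names = [f"f{j}" for j in range(m)]
    data = Dataset.from_arrays(X, y, names, [NUMERIC] * m)
    return SyntheticData(data, mask)


def make_cardinality_null(spec: SimSpec) -> SyntheticData:
    """All-categorical, label-independent columns of differing cardinality."""
    if not spec.cardinalities:
        raise ValueError("cardinalities list must be nonempty")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    y = _balanced_labels(n, spec.n_classes, rng)
    cols = [rng.integers(0, card, size=n) for card in spec.cardinalities]
    X = np.column_stack(cols).astype(np.float64)
    names = [f"card{card}_{j}" for j, card in enumerate(spec.cardinalities)]
    data = Dataset.from_arrays(X, y, names, [CATEGORICAL] * len(cols))
    mask = np.zeros(len(cols), dtype=bool)
    return SyntheticData(data, mask)


def make_cardinality_power(spec: SimSpec) -> SyntheticData:
    """One label-associated binary column plus categorical noise columns.

    The informative column equals a binarized class indicator with
    probability 0.5 + association, independently per sample.
    """
    if not spec.cardinalities:
        raise ValueError("cardinalities list must be nonempty")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    y = _balanced_labels(n, spec.n_classes, rng)
    y_bin = (y > 0).astype(np.int64)
    agree = rng.random(n) < (0.5 + spec.association)
    informative = np.where(agree, y_bin, 1 - y_bin)
    cols = [informative] + [rng.integers(0, card, size=n) for card in spec.cardinalities]
    X = np.column_stack(cols).astype(np.float64)
    names = ["signal"] + [f"card{card}_{j}" for j, card in enumerate(spec.cardinalities)]
    data = Dataset.from_arrays(X, y, names, [CATEGORICAL] * len(cols))
    mask = np.zeros(len(cols), dtype=bool)
    mask[0] = True
    return SyntheticData(data, mask)
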