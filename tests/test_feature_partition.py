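import numpy as np
import pytest

import xrf
from xrf import Dataset
from xrf.feature_partition import (
    FeaturePartition,
    PartitionSampler,
    SubspacePlan,
    chi_square_score,
    filter_informative,
    partition_features,
    sample_subspace,
    subspace_sizes,
)
from xrf.shadow_weighting import FeatureWeights, ImportanceReplicates
from xrf._rng import NodeRng


def weights_from(p_values):
    m = len(p_values)
    reps = ImportanceReplicates(np.zeros((2, m)), np.zeros((2, m)), np.zeros(2))
    return FeatureWeights(np.asarray(p_values, float), np.zeros(m), reps)


def textbook_chi2(table):
    """Independent direct evaluation of sum (O-E)^2 / E."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / n
            stat += (table[i, j] - e) ** 2 / e
    return stat


class TestFilterInformative:
    def test_basic_cut(self):
        inf, disc = filter_informative(weights_from([0.01, 0.20]), 0.05)
        assert inf.tolist() == [0] and disc.tolist() == [1]

    def test_boundary_p_equal_theta_is_kept(self):
        inf, disc = filter_informative(weights_from([0.05, 0.051]), 0.05)
        assert inf.tolist() == [0] and disc.tolist() == [1]

    def test_all_discarded(self):
        inf, disc = filter_informative(weights_from([0.5, 0.9]), 0.05)
        assert inf.size == 0 and disc.tolist() == [0, 1]

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            filter_informative(weights_from([0.5]), 0.0)


class TestChiSquare:
    def test_independent_table(self):
        v = np.array([0.0] * 10 + [1.0] * 10)
        y = np.array(([0] * 5 + [1] * 5) * 2)
        stat, p = chi_square_score(v, y, kind="categorical")
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_diagonal_two_class(self):
        v = np.array([0.0] * 10 + [1.0] * 10)
        y = np.array([0] * 10 + [1] * 10)
        stat, _ = chi_square_score(v, y, kind="categorical")
        assert stat == pytest.approx(20.0)

    def test_diagonal_three_class(self):
        # 3x3 diagonal, 4 per class: chi2 = N*(k-1) = 24
        v = np.repeat([0.0, 1.0, 2.0], 4)
        y = np.repeat([0, 1, 2], 4)
        stat, _ = chi_square_score(v, y, kind="categorical")
        assert stat == pytest.approx(24.0)

    def test_matches_textbook_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            r, c = rng.integers(2, 5, size=2)
            table = rng.integers(1, 12, size=(r, c))
            codes = np.repeat(np.arange(r), table.sum(axis=1))
            labels = np.concatenate([np.repeat(np.arange(c), row) for row in table])
            stat, _ = chi_square_score(codes.astype(float), labels, kind="categorical")
            assert stat == pytest.approx(textbook_chi2(table), rel=1e-9)

    def test_numeric_binning_detects_separation(self):
        rng = np.random.default_rng(2)
        y = np.arange(100) % 2
        v = rng.standard_normal(100) + 3.0 * y
        stat, p = chi_square_score(v, y, n_bins=10, kind="numeric")
        assert p < 1e-6

    def test_degenerate_single_bin(self):
        stat, p = chi_square_score(np.ones(10), np.arange(10) % 2, kind="numeric")
        assert (stat, p) == (0.0, 1.0)


class TestPartitionFeatures:
    def test_strong_weak_split(self, noisy_separable):
        w = weights_from([0.01] * noisy_separable.n_features)
        part = partition_features([0, 1, 2], noisy_separable, 0.05, w)
        # columns 0 and 1 carry a 3-sigma class shift, column 2 is noise
        assert 0 in part.strong and 1 in part.strong
        assert 2 in part.weak
        assert set(part.informative) == set(part.strong) | set(part.weak)

    def test_partition_invariants_enforced(self):
        with pytest.raises(ValueError):
            FeaturePartition(
                informative=[0, 1], strong=[0], weak=[0, 1], discarded=[2],
                wilcoxon_p=np.zeros(3),
            )

    def test_feature_order_invariance(self, noisy_separable):
        w = weights_from([0.01] * noisy_separable.n_features)
        p1 = partition_features([2, 0, 1], noisy_separable, 0.05, w)
        p2 = partition_features([0, 1, 2], noisy_separable, 0.05, w)
        assert np.array_equal(p1.strong, p2.strong)
        assert np.array_equal(p1.weak, p2.weak)


def make_partition(n_strong, n_weak, n_total=None):
    n_total = n_total or (n_strong + n_weak)
    strong = np.arange(n_strong)
    weak = np.arange(n_strong, n_strong + n_weak)
    informative = np.arange(n_strong + n_weak)
    discarded = np.arange(n_strong + n_weak, n_total)
    return FeaturePartition(
        informative=informative, strong=strong, weak=weak,
        discarded=discarded, wilcoxon_p=np.zeros(n_total),
    )


class TestSubspaceSizes:
    @pytest.mark.parametrize(
        "mtry,ns,nw,expected",
        [
            (10, 60, 40, (6, 4)),
            (5, 30, 0, (5, 0)),
            (3, 1, 99, (1, 2)),
            (2, 100, 1, (1, 1)),
            (1, 5, 5, (1, 0)),   # single slot -> equal fractions, strong wins tie
        ],
    )
    def test_allocations(self, mtry, ns, nw, expected):
        plan = subspace_sizes(mtry, make_partition(ns, nw))
        assert (plan.mtry_s, plan.mtry_w) == expected
        assert plan.mtry == mtry

    def test_mtry_exceeding_informative_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            subspace_sizes(5, make_partition(2, 2))

    def test_strong_floor_guarantee(self):
        # every nonempty group gets >= 1 slot whenever mtry >= 2
        rng = np.random.default_rng(0)
        for _ in range(100):
            ns = int(rng.integers(1, 50))
            nw = int(rng.integers(1, 50))
            mtry = int(rng.integers(2, ns + nw + 1))
            plan = subspace_sizes(mtry, make_partition(ns, nw))
            assert plan.mtry_s >= 1 and plan.mtry_w >= 1
            assert plan.mtry_s <= ns and plan.mtry_w <= nw
            assert plan.mtry == mtry


class TestSampleSubspace:
    def test_exhaustive_strong_draw(self):
        part = make_partition(2, 5)
        plan = SubspacePlan(2, 1)
        rng = np.random.default_rng(0)
        for _ in range(50):
            sub = sample_subspace(plan, part, rng)
            assert {0, 1} <= set(sub.tolist())

    def test_invariants(self):
        part = make_partition(5, 10)
        plan = subspace_sizes(4, part)
        rng = np.random.default_rng(1)
        informative = set(part.informative.tolist())
        for _ in range(200):
            sub = sample_subspace(plan, part, rng)
            assert len(sub) == plan.mtry
            assert len(set(sub.tolist())) == len(sub)
            assert set(sub.tolist()) <= informative

    def test_hypergeometric_frequency(self):
        part = make_partition(5, 5)
        plan = SubspacePlan(2, 1)
        rng = np.random.default_rng(3)
        hits = np.zeros(5)
        n_draws = 10_000
        for _ in range(n_draws):
            sub = sample_subspace(plan, part, rng)
            for j in sub:
                if j < 5:
                    hits[j] += 1
        freqs = hits / n_draws
        assert np.allclose(freqs, 0.4, atol=0.02)

    def test_partition_sampler_contract(self):
        part = make_partition(3, 7)
        plan = subspace_sizes(4, part)
        sampler = PartitionSampler(plan, part)
        informative = set(part.informative.tolist())
        for node_id in range(100):
            sub = sampler(np.arange(10), NodeRng(12345, node_id))
            assert len(sub) == plan.mtry
            assert len(set(sub.tolist())) == len(sub)
            assert set(sub.tolist()) <= informative
            assert any(j in set(part.strong.tolist()) for j in sub)

    def test_inconsistent_plan_rejected(self):
        part = make_partition(1, 2)
        with pytest.raises(ValueError, match="inconsistent"):
            sample_subspace(SubspacePlan(2, 1), part, np.random.default_rng(0))
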