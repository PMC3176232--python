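import math
import random

import numpy as np
import pytest
from scipy import stats

from popgenscan.coalescent import (CONSTANT_SIZE, CoalescentConfig,
                                   DemographyModel, NullDistribution,
                                   demography_from_row, drop_mutations,
                                   empirical_p, null_distribution,
                                   replicate_statistics, simulate_genealogy,
                                   window_confidence_bands)
from popgenscan.diversity import NeutralityConstants


class TestGenealogy:
    def test_pairwise_tmrca_expectation(self):
        rng = random.Random(1)
        vals = [simulate_genealogy(2, CONSTANT_SIZE, rng).tmrca
                for _ in range(50_000)]
        se = np.std(vals) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.5) < 3 * se

    def test_total_length_expectation(self):
        # E[T_total] = a_n in units of 4N0 generations
        rng = random.Random(2)
        n = 10
        vals = [simulate_genealogy(n, CONSTANT_SIZE, rng).total_length
                for _ in range(50_000)]
        se = np.std(vals) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - NeutralityConstants.from_n(n).a1) < 3 * se

    def test_bottleneck_shortens_tmrca(self):
        rng = random.Random(3)
        bottleneck = DemographyModel(((0.0, 1.0), (0.05, 0.02), (0.1, 1.0)))
        t_const = np.mean([simulate_genealogy(10, CONSTANT_SIZE, rng).tmrca
                           for _ in range(5000)])
        t_bott = np.mean([simulate_genealogy(10, bottleneck, rng).tmrca
                          for _ in range(5000)])
        assert t_bott < t_const

    def test_branches_partition_leaves(self):
        rng = random.Random(4)
        tree = simulate_genealogy(8, CONSTANT_SIZE, rng)
        assert len(tree.branches) == 14
        leaf_branches = [m for m, _ in tree.branches if m.bit_count() == 1]
        assert sorted(leaf_branches) == [1 << i for i in range(8)]

    def test_demography_validation(self):
        with pytest.raises(ValueError):
            DemographyModel(((0.5, 1.0),))
        with pytest.raises(ValueError):
            DemographyModel(((0.0, 1.0), (0.0, 0.5)))
        with pytest.raises(ValueError):
            DemographyModel(((0.0, -1.0),))

    def test_demography_from_posterior_row(self):
        d = demography_from_row({"start_1": 0.05, "size_1": 0.1,
                                 "start_2": 0.08, "size_2": 0.9})
        assert d.epochs == ((0.0, 1.0), (0.05, 0.1), (0.08, 0.9))


class TestMutations:
    def test_fixed_S_always_sums_to_S(self):
        rng = random.Random(5)
        for _ in range(200):
            tree = simulate_genealogy(7, CONSTANT_SIZE, rng)
            xi = drop_mutations(tree, "fixed_S", 7, rng)
            assert xi.sum() == 7

    def test_watterson_expectation_in_theta_mode(self):
        rng = random.Random(6)
        n, theta = 10, 5.0
        S = []
        for _ in range(10_000):
            tree = simulate_genealogy(n, CONSTANT_SIZE, rng)
            S.append(drop_mutations(tree, "theta", theta, rng).sum())
        se = np.std(S) / math.sqrt(len(S))
        expected = theta * NeutralityConstants.from_n(n).a1
        assert abs(np.mean(S) - expected) < 3 * se

    def test_star_tree_mutations_are_singletons(self):
        # hand-built star genealogy: every branch subtends one leaf
        from popgenscan.coalescent import Genealogy
        star = Genealogy(n=5, branches=[(1 << i, 1.0) for i in range(5)],
                         tmrca=1.0)
        rng = random.Random(7)
        xi = drop_mutations(star, "fixed_S", 12, rng)
        assert xi[0] == 12 and xi[1:].sum() == 0


class TestReproducibility:
    def test_identical_config_identical_replicates(self):
        cfg = CoalescentConfig(n=12, mode="fixed_S", value=9, replicates=500,
                               seed=42)
        a = replicate_statistics(cfg, "D")
        b = replicate_statistics(cfg, "D")
        assert np.array_equal(a, b, equal_nan=True)


class TestMsprimeOracle:
    """Distribution of Tajima's D vs independent msprime genealogies."""

    @pytest.mark.parametrize("n,S", [(10, 12), (24, 45), (54, 87)])
    def test_fixed_S_distribution_matches_msprime(self, n, S):
        import msprime
        from popgenscan.diversity import sfs_theta_pi, tajimas_D
        R = 4000
        cfg = CoalescentConfig(n=n, mode="fixed_S", value=S, replicates=R,
                               seed=100 + n)
        mine = replicate_statistics(cfg, "D")
        rng = np.random.default_rng(1234 + n)
        other = np.empty(R)
        reps = msprime.sim_ancestry(samples=n, ploidy=1, num_replicates=R,
                                    random_seed=999 + n)
        for r, ts in enumerate(reps):
            tree = ts.first()
            counts, lens = [], []
            for u in tree.nodes():
                if tree.parent(u) != -1:
                    k = tree.num_samples(u)
                    if 1 <= k <= n - 1:
                        counts.append(k)
                        lens.append(tree.branch_length(u))
            probs = np.array(lens) / np.sum(lens)
            muts = rng.multinomial(S, probs)
            xi = np.zeros(n - 1, dtype=int)
            for k, m in zip(counts, muts):
                xi[k - 1] += m
            other[r] = tajimas_D(S, sfs_theta_pi(xi, n), n)
        p = stats.ks_2samp(mine, other).pvalue
        assert p > 0.01


class TestNullDistribution:
    def test_extreme_observation_minimal_p(self):
        cfg = CoalescentConfig(n=10, mode="fixed_S", value=8,
                               replicates=9999, seed=8)
        nd = null_distribution(cfg, "D", observed=-50.0)
        assert nd.p_one_tailed == pytest.approx(1 / 10_000)

    def test_median_observation_p_near_one(self):
        cfg = CoalescentConfig(n=10, mode="fixed_S", value=8,
                               replicates=999, seed=9)
        sims = replicate_statistics(cfg, "D")
        nd = null_distribution(cfg, "D", observed=float(np.median(sims)))
        assert nd.p_two_tailed > 0.9

    def test_empirical_p_formula(self):
        values = np.arange(1.0, 100.0)          # 99 replicates
        p_one, p_two = empirical_p(values, 1000.0)
        assert p_one == pytest.approx(1 / 100)
        assert p_two == pytest.approx(2 / 100)

    def test_undefined_replicates_counted(self):
        # theta tiny: most replicates have S=0 and are excluded
        cfg = CoalescentConfig(n=6, mode="theta", value=0.05,
                               replicates=2000, seed=10)
        nd = null_distribution(cfg, "D", observed=0.0)
        assert nd.n_undefined > 0
        assert len(nd.values) + nd.n_undefined == 2000


class TestWindowBands:
    def test_equal_S_windows_share_identical_bands(self):
        bands = window_confidence_bands([5, 9, 5], n=12, statistic="D",
                                        replicates=300, seed=3)
        assert bands[0] == bands[2]
        assert bands[0] != bands[1]

    def test_zero_S_window_gets_null_band(self):
        bands = window_confidence_bands([0, 4], n=12, statistic="D",
                                        replicates=300, seed=3)
        assert math.isnan(bands[0][0]) and math.isnan(bands[0][1])
        assert bands[1][0] < bands[1][1]

    def test_band_width_stable_but_support_coarsens_at_low_S(self):
        """Tajima's normalization keeps the 95% band width roughly constant
        in S; what low-S windows lose is resolution (far fewer attainable D
        values), not nominal band width."""
        widths = []
        for S in (2, 20):
            cfg = CoalescentConfig(n=12, mode="fixed_S", value=S,
                                   replicates=2000, seed=4)
            sims = replicate_statistics(cfg, "D")
            lo, hi = np.quantile(sims, [0.025, 0.975])
            widths.append((hi - lo, len(np.unique(sims))))
        (w2, support2), (w20, support20) = widths
        assert 2.5 < w2 < 4.5 and 2.5 < w20 < 4.5
        assert support2 < support20 / 5
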