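"""Design solvers: minimality, reductions, monotonicity, criteria."""

import math

import numpy as np
import pytest

from maxcontig import (
    PoolDistributionSpec,
    design_fixed_distributed_pool,
    design_single_novel,
    design_stochastic_pool,
    design_uniform_pool,
    materialize_pool,
    pool_success_probability,
    solve_minimum_reads,
    species_success_probability,
    stochastic_pool_success_probability,
)
from maxcontig.pools import SpeciesPool


class TestSolveMinimumReads:
    def test_step_function(self):
        crit = lambda N: 1.0 if N >= 1234 else 0.0
        assert solve_minimum_reads(crit, 0.5) == 1234

    def test_constant_criterion_returns_lower_bound(self):
        assert solve_minimum_reads(lambda N: 1.0, 0.95, lower=7) == 7

    def test_smooth_toy_criterion(self):
        # smallest N with 1 - exp(-N/1000) >= 0.95 is ceil(1000 ln 20)
        crit = lambda N: 1.0 - math.exp(-N / 1000.0)
        assert solve_minimum_reads(crit, 0.95) == 2996

    def test_unreachable_alpha(self):
        with pytest.raises(RuntimeError):
            solve_minimum_reads(lambda N: 0.5, 0.95, ceiling=10**6)


class TestSpeciesSuccess:
    def test_no_reads_no_success(self):
        assert species_success_probability(0, 0.5, 200000, 200, 4) == 0.0

    def test_unreachable_species(self):
        assert species_success_probability(1000, 0.0, 200000, 200, 4) == 0.0

    def test_high_coverage_cap(self):
        # 3x coverage: 3000 reads of 200 on a 200 kb genome
        assert species_success_probability(3000, 1.0, 200000, 200, 4) == 1.0

    def test_uniform_pool_per_species_level(self):
        """At the pool design's read count, each species sits at 0.95**(1/100)."""
        p = species_success_probability(62402, 1.0 / 100, 200000, 200, 4)
        assert p == pytest.approx(0.95 ** (1 / 100), abs=2e-5)


class TestMinimality:
    @pytest.mark.parametrize(
        "designer, crit",
        [
            (
                lambda: design_single_novel(100, 200000, 200, 4, 0.95),
                lambda N: species_success_probability(N, 1 / 101, 200000, 200, 4),
            ),
            (
                lambda: design_uniform_pool(50, 200000, 200, 4, 0.95),
                lambda N: species_success_probability(N, 1 / 50, 200000, 200, 4) ** 50,
            ),
        ],
    )
    def test_boundary(self, designer, crit):
        result = designer()
        N = result.total_reads
        assert crit(N) >= 0.95
        assert crit(N - 1) < 0.95
        assert result.achieved_probability >= 0.95

    def test_distributed_pool_boundary(self):
        spec = PoolDistributionSpec(
            size_min=50000, size_max=350000, species_count=30, pareto_shape=3.5
        )
        result = design_fixed_distributed_pool(spec, 200, 4, 0.95)
        pool = materialize_pool(spec)
        N = result.total_reads
        assert pool_success_probability(N, pool, 200, 4) >= 0.95
        assert pool_success_probability(N - 1, pool, 200, 4) < 0.95
        assert result.expected_reads_per_species.sum() == pytest.approx(N)


class TestReductions:
    def test_uniform_pool_of_one_equals_single_novel_of_zero(self):
        a = design_uniform_pool(1, 200000, 200, 4, 0.95)
        b = design_single_novel(0, 200000, 200, 4, 0.95)
        assert a.total_reads == b.total_reads

    def test_degenerate_distribution_equals_uniform_pool(self):
        spec = PoolDistributionSpec(
            size_min=200000, size_max=200000, species_count=100, pareto_shape=1e9
        )
        a = design_fixed_distributed_pool(spec, 200, 4, 0.95)
        b = design_uniform_pool(100, 200000, 200, 4, 0.95)
        assert a.total_reads == b.total_reads

    def test_poisson_mixture_matches_hand_computed_sum(self):
        """The mu=1 mixture equals the hand-built e^{-1} m!-weighted sum."""
        spec_mu = PoolDistributionSpec(
            size_min=100000, size_max=300000, poisson_mean=1.0, pareto_shape=2.0
        )
        full = stochastic_pool_success_probability(500, spec_mu, 200, 4)
        # Poisson(1) pmf by hand: e^{-1} / s!, renormalized over 0..s_max
        s_max = 25
        weights = [math.exp(-1.0) / math.factorial(s) for s in range(s_max + 1)]
        total_w = sum(weights)
        by_hand = weights[0] / total_w
        for s in range(1, s_max + 1):
            pool_s = materialize_pool(spec_mu, pool_size=s)
            by_hand += weights[s] / total_w * pool_success_probability(500, pool_s, 200, 4)
        assert full == pytest.approx(by_hand, abs=1e-9)

    def test_two_identical_species_square_the_single_probability(self):
        pool = SpeciesPool(
            genome_sizes=np.array([200000.0, 200000.0]),
            abundances=np.array([0.5, 0.5]),
            allocation_probs=np.array([0.5, 0.5]),
        )
        single = species_success_probability(2000, 0.5, 200000, 200, 4)
        assert pool_success_probability(2000, pool, 200, 4) == pytest.approx(single**2)


class TestMonotonicity:
    def test_reads_increase_with_alpha(self):
        lo = design_single_novel(100, 200000, 200, 4, 0.50).total_reads
        hi = design_single_novel(100, 200000, 200, 4, 0.95).total_reads
        assert lo < hi

    def test_reads_increase_with_pool_size_k_and_genome(self):
        base = design_uniform_pool(50, 200000, 200, 4, 0.95).total_reads
        assert design_uniform_pool(100, 200000, 200, 4, 0.95).total_reads > base
        assert design_uniform_pool(50, 200000, 200, 5, 0.95).total_reads > base
        assert design_uniform_pool(50, 400000, 200, 4, 0.95).total_reads > base

    def test_stochastic_exceeds_fixed(self):
        """Pool-size uncertainty costs reads (Poisson vs point mass)."""
        fixed = design_fixed_distributed_pool(
            PoolDistributionSpec(
                size_min=50000, size_max=350000, species_count=50,
                target_max_abundance=0.05,
            ),
            200, 4, 0.95,
        ).total_reads
        stoch = design_stochastic_pool(
            PoolDistributionSpec(
                size_min=50000, size_max=350000, poisson_mean=50.0,
                target_max_abundance=0.05,
            ),
            200, 4, 0.95,
        ).total_reads
        assert stoch > fixed


def test_invalid_parameters():
    with pytest.raises(ValueError):
        design_single_novel(-1, 200000, 200, 4, 0.95)
    with pytest.raises(ValueError):
        design_uniform_pool(100, 200000, 200, 4, 1.0)  # alpha must be < 1
    with pytest.raises(ValueError):
        design_uniform_pool(100, 200000, 200, 1, 0.95)  # k must be >= 2
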