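"""Minimum-read-count solvers for four metagenome experimental designs.

All four designs ask for the smallest total read count N such that, with
confidence alpha, every targeted species yields at least one contig of k
read-lengths.  Reads are allocated to species multinomially with
probabilities ``pi_i``; the solvers use the plug-in expected allocation
``n_i = N pi_i`` (real-valued) inside the single-genome occupancy model.

Variants, in increasing difficulty:

1. single-novel  — one novel species of genome length g pooled in equal
   proportion with S known like-sized species; only the novel one must
   yield the contig.  Criterion:  P1(N/(S+1)) >= alpha.
2. uniform-pool  — S novel species of equal size and abundance, all must
   yield contigs.  Criterion:  P1(N/S)**S >= alpha.
3. fixed-distributed-pool — S novel species with quantile-assigned genome
   sizes and Pareto rank abundances.  Criterion:
   prod_i P1_i(N pi_i) >= alpha.
4. stochastic-pool — the pool size itself is Poisson(mu); the criterion is
   the Poisson-weighted mixture of variant-3 criteria over pool sizes,
   with the Pareto shape recalibrated at each pool size so the most
   abundant species stays at the target fraction (2.5% by default).

Species whose expected coverage ``n_i l / g_i`` exceeds a configurable
high-coverage cap (default 3.0x) are assigned success probability exactly
1: the occupancy model understates contig sizes at high coverage, and such
heavily sampled species are certain to assemble in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .occupancy import SequencingSpec, prob_max_contig_ge
from .pools import PoolDistributionSpec, SpeciesPool, materialize_pool, poisson_pool_weights

logger = logging.getLogger("maxcontig")

__all__ = [
    "DesignProblem",
    "DesignResult",
    "HIGH_COVERAGE_CAP",
    "species_success_probability",
    "design_single_novel",
    "design_uniform_pool",
    "pool_success_probability",
    "design_fixed_distributed_pool",
    "stochastic_pool_success_probability",
    "design_stochastic_pool",
    "solve_minimum_reads",
]

#: Expected-coverage threshold above which a species is treated as certain
#: to yield the target contig.  The occupancy model breaks down by ~4x
#: coverage; 3.0x keeps the cap safely inside the broken regime.
HIGH_COVERAGE_CAP = 3.0

#: Ceiling for the bracket search (far above any design in the tables).
_MAX_READS = 1 << 40


@dataclass(frozen=True)
class DesignProblem:
    """A design variant with its parameters (record of what was solved)."""

    variant: str
    read_length: int
    min_contig: int
    confidence: float
    species_count: Optional[int] = None
    poisson_mean: Optional[float] = None
    genome_length: Optional[float] = None
    pool_spec: Optional[PoolDistributionSpec] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie strictly between 0 and 1")
        if self.min_contig < 2:
            raise ValueError("min_contig must be >= 2 (the model is unreliable at k=1)")


@dataclass(frozen=True)
class DesignResult:
    """Solved design: minimum total reads and per-species diagnostics."""

    problem: DesignProblem
    total_reads: int
    achieved_probability: float
    expected_reads_per_species: np.ndarray
    per_species_success: np.ndarray
    capped_species: tuple = ()

    def summary_row(self) -> dict:
        p = self.problem
        return {
            "variant": p.variant,
            "S_or_mu": p.species_count if p.species_count is not None else p.poisson_mean,
            "k": p.min_contig,
            "alpha": p.confidence,
            "read_length": p.read_length,
            "total_reads": self.total_reads,
            "achieved_probability": self.achieved_probability,
            "n_capped_species": len(self.capped_species),
        }


def _success_vector(
    expected_reads: np.ndarray,
    genome_lengths: np.ndarray,
    read_length: int,
    k: int,
    cap: float = HIGH_COVERAGE_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-species success probabilities with the coverage cap.

    Returns ``(probs, capped_mask)``.  This is the plug-in evaluation of
    the single-genome survival probability at the expected allocations.
    """
    n = np.asarray(expected_reads, dtype=float)
    g = np.asarray(genome_lengths, dtype=float)
    T = g / read_length
    B = 2.0 * T - 1.0
    p = -np.expm1(n * np.log1p(-1.0 / B))
    lam = B * (1.0 - p) * p**k
    probs = -np.expm1(-lam)
    probs = np.where(k > T, 0.0, probs)
    coverage = n * read_length / g
    capped = coverage >= cap
    return np.where(capped, 1.0, probs), capped


def species_success_probability(
    total_reads: float,
    allocation_prob: float,
    genome_length: float,
    read_length: int,
    k: int,
    cap: float = HIGH_COVERAGE_CAP,
) -> float:
    """P(species yields a contig >= k) at expected allocation N*pi.

    Returns exactly 1 when the species' expected coverage reaches the
    high-coverage cap, and 0 (with a warning) for an unreachable species
    (allocation probability 0).
    """
    if not 0.0 <= allocation_prob <= 1.0:
        raise ValueError("allocation_prob must lie in [0, 1]")
    if allocation_prob == 0.0:
        logger.warning("species with zero allocation probability is unreachable")
        return 0.0
    n = total_reads * allocation_prob
    if n * read_length / genome_length >= cap:
        return 1.0
    return prob_max_contig_ge(SequencingSpec(genome_length, read_length, n), k)


def solve_minimum_reads(
    criterion: Callable[[int], float],
    alpha: float,
    lower: int = 1,
    upper_hint: Optional[int] = None,
    ceiling: int = _MAX_READS,
) -> int:
    """Smallest integer N with criterion(N) >= alpha.

    The criterion must be nondecreasing in N over the searched range.
    Brackets by exponential growth from ``upper_hint`` (or ``lower``),
    then bisects.  Comparisons use >= with no floating-point slack.
    """
    if criterion(lower) >= alpha:
        return lower
    hi = max(upper_hint or lower * 2, lower + 1)
    while criterion(hi) < alpha:
        hi *= 2
        if hi > ceiling:
            raise RuntimeError(f"criterion never reaches alpha={alpha} below {ceiling}")
    lo = lower  # invariant: criterion(lo) < alpha <= criterion(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if criterion(mid) >= alpha:
            hi = mid
        else:
            lo = mid
    return hi


def _finish(problem: DesignProblem, N: int, pool: SpeciesPool, cap: float) -> DesignResult:
    n = N * pool.allocation_probs
    probs, capped = _success_vector(
        n, pool.genome_sizes, problem.read_length, problem.min_contig, cap
    )
    return DesignResult(
        problem=problem,
        total_reads=N,
        achieved_probability=float(np.prod(probs)),
        expected_reads_per_species=n,
        per_species_success=probs,
        capped_species=tuple(np.flatnonzero(capped)),
    )


def design_single_novel(
    known_species: int,
    genome_length: float,
    read_length: int,
    k: int,
    alpha: float,
    cap: float = HIGH_COVERAGE_CAP,
) -> DesignResult:
    """Smallest N detecting one novel species among ``known_species`` knowns.

    All S+1 species share the genome length and abundance, so the novel
    species receives N/(S+1) reads in expectation and only it must yield
    the contig.
    """
    if known_species < 0:
        raise ValueError("known_species must be >= 0")
    S1 = known_species + 1
    crit = lambda N: species_success_probability(
        N, 1.0 / S1, genome_length, read_length, k, cap
    )
    N = solve_minimum_reads(crit, alpha, upper_hint=S1 * 100)
    problem = DesignProblem(
        variant="single-novel",
        read_length=read_length,
        min_contig=k,
        confidence=alpha,
        species_count=known_species,
        genome_length=genome_length,
    )
    pool = SpeciesPool(
        genome_sizes=np.full(S1, float(genome_length)),
        abundances=np.full(S1, 1.0 / S1),
        allocation_probs=np.full(S1, 1.0 / S1),
    )
    result = _finish(problem, N, pool, cap)
    # achieved probability is the novel species' alone, not a product
    return DesignResult(
        problem=problem,
        total_reads=N,
        achieved_probability=float(result.per_species_success[0]),
        expected_reads_per_species=result.expected_reads_per_species,
        per_species_success=result.per_species_success,
        capped_species=result.capped_species,
    )


def design_uniform_pool(
    species: int,
    genome_length: float,
    read_length: int,
    k: int,
    alpha: float,
    cap: float = HIGH_COVERAGE_CAP,
) -> DesignResult:
    """Smallest N giving every one of S equal species a contig >= k.

    Criterion: the S-fold power of the per-species success probability at
    allocation 1/S, using independence of assemblies across species
    conditional on the allocations.
    """
    if species < 1:
        raise ValueError("species must be >= 1")
    crit = lambda N: species_success_probability(
        N, 1.0 / species, genome_length, read_length, k, cap
    ) ** species
    N = solve_minimum_reads(crit, alpha, upper_hint=species * 100)
    problem = DesignProblem(
        variant="uniform-pool",
        read_length=read_length,
        min_contig=k,
        confidence=alpha,
        species_count=species,
        genome_length=genome_length,
    )
    pool = SpeciesPool(
        genome_sizes=np.full(species, float(genome_length)),
        abundances=np.full(species, 1.0 / species),
        allocation_probs=np.full(species, 1.0 / species),
    )
    return _finish(problem, N, pool, cap)


def pool_success_probability(
    total_reads: float,
    pool: SpeciesPool,
    read_length: int,
    k: int,
    cap: float = HIGH_COVERAGE_CAP,
) -> float:
    """P(every species in a concrete pool yields a contig >= k).

    Product over species of the plug-in success probabilities at expected
    allocations ``N pi_i``; high-coverage species contribute factor 1.  An
    empty pool returns 1 (vacuous product) with a warning.
    """
    if len(pool) == 0:
        logger.warning("empty pool: success probability is vacuously 1")
        return 1.0
    n = total_reads * pool.allocation_probs
    probs, _ = _success_vector(n, pool.genome_sizes, read_length, k, cap)
    return float(np.prod(probs))


def design_fixed_distributed_pool(
    pool_spec: PoolDistributionSpec,
    read_length: int,
    k: int,
    alpha: float,
    cap: float = HIGH_COVERAGE_CAP,
) -> DesignResult:
    """Smallest N for a fixed-size pool with distributed sizes/abundances."""
    if pool_spec.species_count is None:
        raise ValueError("fixed-distributed design needs a fixed species_count")
    pool = materialize_pool(pool_spec)
    crit = lambda N: pool_success_probability(N, pool, read_length, k, cap)
    N = solve_minimum_reads(crit, alpha, upper_hint=len(pool) * 100)
    problem = DesignProblem(
        variant="fixed-distributed-pool",
        read_length=read_length,
        min_contig=k,
        confidence=alpha,
        species_count=pool_spec.species_count,
        pool_spec=pool_spec,
    )
    return _finish(problem, N, pool, cap)


def stochastic_pool_success_probability(
    total_reads: float,
    pool_spec: PoolDistributionSpec,
    read_length: int,
    k: int,
    cap: float = HIGH_COVERAGE_CAP,
    mass_tolerance: float = 1e-9,
    _pool_cache: Optional[dict] = None,
) -> float:
    """Mixture success probability over a Poisson-distributed pool size.

    ``sum_s w_s * P(all s species succeed | pool materialized at s)`` over
    the truncated Poisson support.  At each pool size the pool is rebuilt
    by quantile assignment; if the spec targets a maximum abundance the
    Pareto shape is recalibrated per pool size.  s=0 contributes a vacuous
    factor 1.
    """
    if pool_spec.poisson_mean is None:
        raise ValueError("stochastic design needs poisson_mean")
    s_values, weights = poisson_pool_weights(pool_spec.poisson_mean, mass_tolerance)
    cache = _pool_cache if _pool_cache is not None else {}
    total = 0.0
    for s, w in zip(s_values, weights):
        if s == 0:
            total += w
            continue
        if s not in cache:
            cache[s] = materialize_pool(pool_spec, pool_size=int(s))
        total += w * pool_success_probability(total_reads, cache[s], read_length, k, cap)
    return total


def design_stochastic_pool(
    pool_spec: PoolDistributionSpec,
    read_length: int,
    k: int,
    alpha: float,
    cap: float = HIGH_COVERAGE_CAP,
    mass_tolerance: float = 1e-9,
) -> DesignResult:
    """Smallest N for a Poisson-random pool with distributed sizes/abundances."""
    cache: dict = {}
    crit = lambda N: stochastic_pool_success_probability(
        N, pool_spec, read_length, k, cap, mass_tolerance, _pool_cache=cache
    )
    mu = pool_spec.poisson_mean
    N = solve_minimum_reads(crit, alpha, upper_hint=int(mu * 100))
    problem = DesignProblem(
        variant="stochastic-pool",
        read_length=read_length,
        min_contig=k,
        confidence=alpha,
        poisson_mean=mu,
        pool_spec=pool_spec,
    )
    # report diagnostics at the expected pool size
    s_exp = max(int(round(mu)), 1)
    pool = cache.get(s_exp) or materialize_pool(pool_spec, pool_size=s_exp)
    n = N * pool.allocation_probs
    probs, capped = _success_vector(n, pool.genome_sizes, read_length, k, cap)
    return DesignResult(
        problem=problem,
        total_reads=N,
        achieved_probability=crit(N),
        expected_reads_per_species=n,
        per_species_success=probs,
        capped_species=tuple(np.flatnonzero(capped)),
    )
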