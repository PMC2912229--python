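"""Species-pool construction by quantile assignment.

A pool of S species is given genome sizes equal to the ``i/(S+1)``
quantiles (i = 1..S) of a Uniform(g_min, g_max) distribution and
commonality-normalized abundances ``x_i`` equal to the ``i/(S+1)``
quantiles of a Pareto distribution with scale 1 and shape ``beta``
(survival quantile ``x = (1-u)**(-1/beta)``), so the pool collectively
matches both marginals.  Percentage abundances are ``a = x / sum(x)``.
With no joint size-abundance model, the ranks are paired either
"small-abundant" (greater abundances to smaller genomes, the default used
throughout the worked examples) or "large-abundant" (the mirror pairing).

A read drawn at random from the pooled DNA originates from species i with
allocation probability ``pi_i = a_i g_i / G`` where ``G = sum_j a_j g_j``
is the abundance-normalized total genome size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PoolDistributionSpec",
    "SpeciesPool",
    "uniform_size_quantiles",
    "pareto_rank_abundances",
    "calibrate_pareto_shape",
    "max_rank_abundance",
    "assemble_pool",
    "poisson_pool_weights",
    "materialize_pool",
]

Ordering = Literal["small-abundant", "large-abundant"]


@dataclass(frozen=True)
class SpeciesPool:
    """A concrete pool: sizes, abundances and read-allocation probabilities.

    ``genome_sizes`` are in bases (real-valued: quantiles are not rounded;
    simulators round to integer bases).  ``abundances`` sum to 1.
    ``allocation_probs`` are ``a_i g_i / sum_j a_j g_j`` and sum to 1.
    """

    genome_sizes: np.ndarray
    abundances: np.ndarray
    allocation_probs: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genome_sizes, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        pi = np.asarray(self.allocation_probs, dtype=float)
        if not (len(g) == len(a) == len(pi)):
            raise ValueError("pool field lengths differ")
        object.__setattr__(self, "genome_sizes", g)
        object.__setattr__(self, "abundances", a)
        object.__setattr__(self, "allocation_probs", pi)

    def __len__(self) -> int:
        return len(self.genome_sizes)

    @property
    def normalized_total_genome_size(self) -> float:
        """G = sum_j a_j g_j, the abundance-normalized total genome size."""
        return float(np.sum(self.abundances * self.genome_sizes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": np.arange(1, len(self) + 1),
                "genome_size": self.genome_sizes,
                "abundance": self.abundances,
                "allocation_prob": self.allocation_probs,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpeciesPool":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"genome_size", "abundance"}
        if not required.issubset(df.columns):
            raise ValueError(f"species table must have columns {sorted(required)}")
        a = df["abundance"].to_numpy(float)
        a = a / a.sum()
        g = df["genome_size"].to_numpy(float)
        pi = a * g / np.sum(a * g)
        return cls(genome_sizes=g, abundances=a, allocation_probs=pi)


@dataclass(frozen=True)
class PoolDistributionSpec:
    """Distributional description of a pool.

    Exactly one of ``species_count`` (fixed S) / ``poisson_mean`` (random,
    Poisson-distributed S) and exactly one of ``pareto_shape`` /
    ``target_max_abundance`` must be given.  Genome sizes are
    Uniform(size_min, size_max) quantiles.
    """

    size_min: float
    size_max: float
    species_count: Optional[int] = None
    poisson_mean: Optional[float] = None
    pareto_shape: Optional[float] = None
    target_max_abundance: Optional[float] = None
    ordering: Ordering = "small-abundant"

    def __post_init__(self) -> None:
        if self.size_min > self.size_max or self.size_min <= 0:
            raise ValueError("need 0 < size_min <= size_max")
        if (self.species_count is None) == (self.poisson_mean is None):
            raise ValueError("give exactly one of species_count / poisson_mean")
        if (self.pareto_shape is None) == (self.target_max_abundance is None):
            raise ValueError("give exactly one of pareto_shape / target_max_abundance")
        if self.species_count is not None and self.species_count < 1:
            raise ValueError("species_count must be >= 1")
        if self.poisson_mean is not None and self.poisson_mean <= 0:
            raise ValueError("poisson_mean must be > 0")
        if self.pareto_shape is not None and self.pareto_shape <= 0:
            raise ValueError("pareto_shape must be > 0")
        if self.ordering not in ("small-abundant", "large-abundant"):
            raise ValueError(f"unknown ordering {self.ordering!r}")


def uniform_size_quantiles(S: int, g_min: float, g_max: float) -> np.ndarray:
    """The S quantiles of Uniform(g_min, g_max) at positions i/(S+1), ascending."""
    if S < 1:
        raise ValueError("S must be >= 1")
    if g_min > g_max:
        raise ValueError("g_min must not exceed g_max")
    u = np.arange(1, S + 1) / (S + 1)
    return g_min + u * (g_max - g_min)


def pareto_rank_abundances(S: int, shape: float) -> tuple[np.ndarray, np.ndarray]:
    """Rank abundances from Pareto(scale 1, shape beta) quantiles.

    Returns ``(x, a)`` with ``x_i = (1 - i/(S+1))**(-1/beta)`` (ascending,
    min ~ the scale 1) and ``a = x / sum(x)``.  The i/(S+1) plotting
    position is load-bearing: it is what makes the most abundant of 100
    species under shape 3.5 represent 2.72% of the sample.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if shape <= 0:
        raise ValueError("shape must be > 0")
    u = np.arange(1, S + 1) / (S + 1)
    x = (1.0 - u) ** (-1.0 / shape)
    return x, x / x.sum()


def max_rank_abundance(S: int, shape: float) -> float:
    """Largest normalized rank abundance for a pool of S species."""
    _, a = pareto_rank_abundances(S, shape)
    return float(a[-1])


def calibrate_pareto_shape(
    S: int, target_max_abundance: float, tol: float = 1e-9
) -> float:
    """Shape beta whose largest rank abundance equals the target.

    The maximum abundance decreases monotonically from 1 (beta -> 0) to
    1/S (beta -> inf), so the root is found by bracketed monotone search.
    Raises if the target is outside (1/S, 1).
    """
    if not 1.0 / S < target_max_abundance < 1.0:
        raise ValueError(
            f"target max abundance must lie in (1/S, 1) = ({1.0 / S:.4g}, 1)"
        )
    f = lambda b: max_rank_abundance(S, b) - target_max_abundance
    # f is decreasing in b: small shape -> heavy tail -> max abundance near 1.
    lo, hi = 1e-3, 1.0
    while f(hi) > 0:
        lo = hi
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("no shape attains the target max abundance")
    return float(optimize.brentq(f, lo, hi, xtol=tol))


def assemble_pool(
    sizes: np.ndarray, abundances: np.ndarray, ordering: Ordering = "small-abundant"
) -> SpeciesPool:
    """Pair sizes with abundances by rank and compute allocation probabilities.

    ``small-abundant`` pairs the largest abundance with the smallest
    genome (rank-reversed); ``large-abundant`` pairs rank-aligned.  Sizes
    are listed ascending in the result either way.
    """
    g = np.sort(np.asarray(sizes, dtype=float))
    a = np.sort(np.asarray(abundances, dtype=float))
    if len(g) != len(a):
        raise ValueError("sizes and abundances must have equal length")
    if ordering == "small-abundant":
        a = a[::-1]
    elif ordering != "large-abundant":
        raise ValueError(f"unknown ordering {ordering!r}")
    a = a / a.sum()
    pi = a * g / np.sum(a * g)
    return SpeciesPool(genome_sizes=g, abundances=a, allocation_probs=pi)


def poisson_pool_weights(
    mean: float, mass_tolerance: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Truncated, renormalized Poisson(mean) pool-size distribution.

    Support runs from 0 to the (1 - mass_tolerance/2) quantile plus a
    buffer, always including s=0, and covers at least ``1 -
    mass_tolerance`` of the mass before renormalization.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if not 0 < mass_tolerance < 1:
        raise ValueError("mass_tolerance must lie in (0, 1)")
    hi = int(stats.poisson.ppf(1.0 - mass_tolerance / 2.0, mean)) + 2
    s = np.arange(0, hi + 1)
    w = stats.poisson.pmf(s, mean)
    if w.sum() < 1.0 - mass_tolerance:
        raise RuntimeError("Poisson truncation failed to capture requested mass")
    return s, w / w.sum()


def materialize_pool(spec: PoolDistributionSpec, pool_size: Optional[int] = None) -> SpeciesPool:
    """Build the concrete quantile-assigned pool for a distribution spec.

    ``pool_size`` overrides the spec's fixed S (used when mixing over a
    random pool size).  If the spec targets a maximum abundance the Pareto
    shape is calibrated for this pool size; when the target is unattainable
    (target <= 1/S) abundances fall back to equal, the closest achievable
    composition.
    """
    S = pool_size if pool_size is not None else spec.species_count
    if S is None:
        raise ValueError("pool size is required (fixed S or explicit override)")
    sizes = uniform_size_quantiles(S, spec.size_min, spec.size_max)
    if spec.pareto_shape is not None:
        _, a = pareto_rank_abundances(S, spec.pareto_shape)
    else:
        target = spec.target_max_abundance
        if target <= 1.0 / S:
            a = np.full(S, 1.0 / S)
        else:
            beta = calibrate_pareto_shape(S, target)
            _, a = pareto_rank_abundances(S, beta)
    return assemble_pool(sizes, a, spec.ordering)
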