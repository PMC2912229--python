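"""Occupancy-model approximation to the maximum contig size distribution.

A genome of length ``g`` sequenced with ``n`` uniformly placed reads of
length ``l`` is discretized into read-sized bins: ``T = g/l`` primary
("Wendl") bins plus ``T - 1`` secondary bins offset by half a read length
("expectation overlap tiling"), ``2T - 1`` bins in total.  Reads are
modeled as landing uniformly in one of the ``2T - 1`` bins; a contig of
``k`` read-lengths corresponds to a run of ``k`` consecutive occupied bins
within either tiling.

With per-bin occupancy probability ``p = 1 - (1 - 1/(2T-1))**n``, the
longest-run (Chen-Stein / Poisson) approximation gives the survival
function of the maximum contig size M, in read-lengths, as

    P(M >= k)  ~=  1 - exp(-lam_W(k)) * exp(-lam_O(k)),
    lam_W(k) = T (1-p) p**k,     lam_O(k) = (T-1) (1-p) p**k,

treating the two tilings as independent.  The model is accurate at low
coverage (well under ~4x); see the methods note for the known bias
directions and the breakdown regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("maxcontig")

__all__ = [
    "SequencingSpec",
    "TilingCounts",
    "MaxContigModel",
    "tiling_counts",
    "occupancy_probability",
    "longest_run_rate",
    "prob_max_contig_ge",
    "max_contig_survival_curve",
]


@dataclass(frozen=True)
class SequencingSpec:
    """One genome's sequencing scenario.

    Parameters
    ----------
    genome_length
        Genome size in bases.  Real-valued sizes are accepted because pool
        genome sizes are set to distribution quantiles.
    read_length
        Read size in bases.
    read_count
        Number of reads.  Fractional values represent expected allocations
        of a multinomially distributed read total and are the normal input
        from the design solvers.
    """

    genome_length: float
    read_length: int
    read_count: float

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.read_length <= 0:
            raise ValueError("genome_length and read_length must be positive")
        if self.read_length > self.genome_length:
            raise ValueError(
                f"read_length {self.read_length} exceeds genome_length "
                f"{self.genome_length}"
            )
        if not (self.read_count >= 0 and math.isfinite(self.read_count)):
            raise ValueError("read_count must be finite and >= 0")

    @property
    def coverage(self) -> float:
        """Depth of coverage n*l/g."""
        return self.read_count * self.read_length / self.genome_length


@dataclass(frozen=True)
class TilingCounts:
    """Bin bookkeeping for the two interleaved discretizations."""

    wendl_bins: int
    overlap_bins: int
    total_bins: int


def tiling_counts(genome_length: float, read_length: int) -> TilingCounts:
    """Integer bin counts for the Wendl and overlap tilings.

    ``wendl_bins = floor(g/l)``, ``overlap_bins = wendl_bins - 1``,
    ``total_bins = 2*wendl_bins - 1``.  Simulators use these discrete
    counts; the analytic rate formulas use the real-valued ``g/l`` (see
    :func:`prob_max_contig_ge`).
    """
    if genome_length <= 0 or read_length <= 0:
        raise ValueError("genome_length and read_length must be positive")
    if read_length > genome_length:
        raise ValueError("read_length must not exceed genome_length")
    T = int(genome_length // read_length)
    return TilingCounts(wendl_bins=T, overlap_bins=T - 1, total_bins=2 * T - 1)


def occupancy_probability(read_count: float, total_bins: float) -> float:
    """Probability that a given bin holds at least one read.

    ``p = 1 - (1 - 1/B)**n`` for ``n`` reads landing uniformly and
    independently over ``B`` equiprobable bins, evaluated for real ``n``
    via ``expm1``/``log1p`` so fractional expected read counts are valid.
    """
    if total_bins < 1:
        raise ValueError("total_bins must be >= 1")
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    if total_bins == 1:
        return 0.0 if read_count == 0 else 1.0
    return -math.expm1(read_count * math.log1p(-1.0 / total_bins))


def longest_run_rate(bins_in_tiling: float, p: float, k: int) -> float:
    """Poisson rate for runs of >= k occupied bins in one tiling.

    Returns ``lam = bins * (1-p) * p**k`` so that the probability of the
    longest run of occupied bins falling short of ``k`` is approximately
    ``exp(-lam)``.  ``bins_in_tiling`` may be real-valued (quantile genome
    sizes need not be multiples of the read length).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    if bins_in_tiling < 1:
        raise ValueError("bins_in_tiling must be >= 1")
    if k > bins_in_tiling:
        logger.warning(
            "run length k=%d exceeds tiling size %s; rate forced to 0", k, bins_in_tiling
        )
        return 0.0
    if p == 0.0:
        return 0.0
    return bins_in_tiling * (1.0 - p) * p**k


@dataclass(frozen=True)
class MaxContigModel:
    """Assembled occupancy model for one sequencing scenario.

    Holds the per-bin occupancy probability and lazily computed per-k run
    rates for the combined tiling.
    """

    spec: SequencingSpec
    occupancy_prob: float
    run_rates: dict = field(default_factory=dict, compare=False)

    @classmethod
    def from_spec(cls, spec: SequencingSpec) -> "MaxContigModel":
        T = spec.genome_length / spec.read_length
        p = occupancy_probability(spec.read_count, 2.0 * T - 1.0)
        return cls(spec=spec, occupancy_prob=p)

    def rate(self, k: int) -> float:
        """Combined-tiling rate lam_W(k) + lam_O(k)."""
        if k not in self.run_rates:
            T = self.spec.genome_length / self.spec.read_length
            lam_w = longest_run_rate(T, self.occupancy_prob, k)
            lam_o = longest_run_rate(T - 1.0, self.occupancy_prob, k) if T > 1 else 0.0
            self.run_rates[k] = lam_w + lam_o
        return self.run_rates[k]


def prob_max_contig_ge(spec: SequencingSpec, k: int) -> float:
    """P(maximum contig >= k read-lengths) under the two-tiling model.

    Combines the Wendl and overlap tilings under the independence
    approximation:  ``1 - exp(-lam_W(k)) * exp(-lam_O(k))``.  The bin
    counts entering the rates are the real-valued ``g/l`` and ``g/l - 1``,
    which avoids step artifacts when genome sizes are distribution
    quantiles.  Returns 0 when ``k`` exceeds the number of Wendl bins (a
    contig cannot exceed the genome).

    The approximation is known to be poor at k=1 (it does not reduce to
    probability 1 for n >= 1); the design solvers only use k >= 2.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    T = spec.genome_length / spec.read_length
    if k > T:
        return 0.0
    if spec.read_count == 0:
        return 0.0
    model = MaxContigModel.from_spec(spec)
    return -math.expm1(-model.rate(k))


def max_contig_survival_curve(spec: SequencingSpec, k_max: int) -> np.ndarray:
    """Vector of P(M >= k) for k = 1..k_max (index 0 <-> k=1)."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    return np.array([prob_max_contig_ge(spec, k) for k in range(1, k_max + 1)])
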