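"""Seeded Monte-Carlo simulators of shotgun assembly contig sizes.

Three single-genome protocols validate the occupancy model:

* ``base``    — reads placed at uniform start positions on a linear genome
  (1-based inclusive starts, reads wholly inside the genome, so g - l + 1
  equiprobable starts); the maximum contig is the longest run of covered
  bases, reported in read-lengths as a real number.  Abutting reads merge;
  a gap of one base splits.
* ``wendl``   — reads dropped uniformly into T = floor(g/l) read-sized
  bins; the maximum contig is the longest run of occupied bins.
* ``overlap`` — reads dropped uniformly into 2T - 1 interleaved bins; runs
  are counted within the T Wendl bins (even indices) and the T - 1 overlap
  bins (odd indices) separately and the larger taken.  Runs alternating
  between tilings are subsets of single-tiling runs and are not counted.

The metagenome protocol assigns each replicate's reads to species
multinomially with the pool's allocation probabilities, places them
base-level on each genome (sizes rounded to integer bases), takes each
species' maximum contig in read-lengths, and records the minimum across
species: the minimax contig size that a pool-wide design guarantees.

All simulators are driven by a single integer seed through numpy's PCG64
generator; identical seed and parameters give bitwise-identical samples.
Species assignment happens before position assignment, in species index
order, which fixes the replicate streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pools import SpeciesPool

__all__ = [
    "SimulationRun",
    "simulate_single_genome",
    "simulate_metagenome_minimax",
    "empirical_cdf",
    "quantiles",
    "longest_covered_run",
]

_SINGLE_MODES = ("base", "wendl", "overlap")


@dataclass(frozen=True)
class SimulationRun:
    """Per-replicate maximum (or minimax) contig sizes plus summaries."""

    mode: str
    parameters: dict
    seed: int
    samples: np.ndarray
    per_species: np.ndarray | None = None  # metagenome mode: reps x species

    def ecdf(self) -> pd.DataFrame:
        return empirical_cdf(self.samples)

    def quantiles(self, probs: Sequence[float] = (0.05, 0.5, 0.95)) -> np.ndarray:
        return quantiles(self.samples, probs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"replicate": np.arange(1, len(self.samples) + 1), "value": self.samples}
        )


def longest_covered_run(starts: np.ndarray, read_length: int) -> int:
    """Longest run of covered bases given read start positions (bases).

    Reads cover ``[s, s + l)``; overlapping or abutting reads merge into
    one contig, a gap of at least one base splits.
    """
    if len(starts) == 0:
        return 0
    s = np.sort(np.asarray(starts))
    ends = np.maximum.accumulate(s + read_length)
    # a new contig begins where a start exceeds the running max end
    breaks = np.flatnonzero(s[1:] > ends[:-1])
    first = np.concatenate(([0], breaks + 1))
    last = np.concatenate((breaks, [len(s) - 1]))
    return int((ends[last] - s[first]).max())


def _longest_true_run(mask: np.ndarray) -> int:
    """Longest run of True in a boolean vector."""
    if not mask.any():
        return 0
    m = mask.astype(np.int8)
    d = np.diff(np.concatenate(([0], m, [0])))
    return int((np.flatnonzero(d == -1) - np.flatnonzero(d == 1)).max())


def simulate_single_genome(
    genome_length: int,
    read_length: int,
    read_count: int,
    replicates: int,
    seed: int,
    mode: str = "base",
) -> SimulationRun:
    """Monte-Carlo maximum contig sizes for one genome, in read-lengths."""
    if mode not in _SINGLE_MODES:
        raise ValueError(f"mode must be one of {_SINGLE_MODES}")
    if read_length > genome_length:
        raise ValueError("read_length must not exceed genome_length")
    if read_count < 0 or replicates < 1:
        raise ValueError("need read_count >= 0 and replicates >= 1")
    rng = np.random.default_rng(seed)
    T = genome_length // read_length
    out = np.empty(replicates)
    for r in range(replicates):
        if read_count == 0:
            out[r] = 0.0
        elif mode == "base":
            starts = rng.integers(0, genome_length - read_length + 1, read_count)
            out[r] = longest_covered_run(starts, read_length) / read_length
        elif mode == "wendl":
            occ = np.bincount(rng.integers(0, T, read_count), minlength=T) > 0
            out[r] = _longest_true_run(occ)
        else:  # overlap
            B = 2 * T - 1
            occ = np.bincount(rng.integers(0, B, read_count), minlength=B) > 0
            out[r] = max(_longest_true_run(occ[0::2]), _longest_true_run(occ[1::2]))
    params = dict(
        genome_length=genome_length,
        read_length=read_length,
        read_count=read_count,
        replicates=replicates,
    )
    return SimulationRun(mode=mode, parameters=params, seed=seed, samples=out)


def simulate_metagenome_minimax(
    total_reads: int,
    pool: SpeciesPool,
    read_length: int,
    replicates: int,
    seed: int,
) -> SimulationRun:
    """Monte-Carlo minimax contig sizes for a concrete species pool.

    Per replicate: reads are assigned to species multinomially with the
    allocation probabilities, placed uniformly (base-level) on each
    genome, the per-species maximum contig computed in read-lengths, and
    the minimum across species recorded.  A species drawing zero reads
    contributes a maximum contig of 0.
    """
    if len(pool) == 0:
        raise ValueError("pool must contain at least one species")
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = np.rint(pool.genome_sizes).astype(np.int64)
    if (sizes < read_length).any():
        raise ValueError("every genome must be at least one read long")
    S = len(pool)
    per_species = np.empty((replicates, S))
    for r in range(replicates):
        counts = rng.multinomial(total_reads, pool.allocation_probs)
        for i in range(S):
            if counts[i] == 0:
                per_species[r, i] = 0.0
            else:
                starts = rng.integers(0, sizes[i] - read_length + 1, counts[i])
                per_species[r, i] = longest_covered_run(starts, read_length) / read_length
    params = dict(
        total_reads=total_reads,
        species=S,
        read_length=read_length,
        replicates=replicates,
    )
    return SimulationRun(
        mode="metagenome-minimax",
        parameters=params,
        seed=seed,
        samples=per_species.min(axis=1),
        per_species=per_species,
    )


def empirical_cdf(samples: np.ndarray) -> pd.DataFrame:
    """Right-continuous ECDF table with columns ``value`` and ``ecdf``."""
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("samples must be nonempty")
    values, counts = np.unique(s, return_counts=True)
    return pd.DataFrame({"value": values, "ecdf": np.cumsum(counts) / s.size})


def quantiles(samples: np.ndarray, probs: Sequence[float]) -> np.ndarray:
    """Sample quantiles with linear interpolation (numpy default)."""
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("samples must be nonempty")
    return np.quantile(s, probs)
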