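# Methods

## Model

The sequencing of a genome of `g` bases with `n` reads of fixed length
`ℓ` is modeled as an occupancy process. The genome is discretized twice:
into `T = g/ℓ` read-sized bins (the primary, "Wendl" tiling) and into
`T − 1` read-sized bins offset by `ℓ/2` (the "expectation overlap"
tiling, motivated by the average half-read overlap of two reads that
assemble into one contig). Each read occupies one of the `B = 2T − 1`
bins uniformly at random, so a given bin is occupied with probability

    p = 1 − (1 − 1/B)^n ,

evaluated for real `n` (design solvers feed expected allocations, which
are not integers). A contig of `k` read-lengths corresponds to a run of
`k` consecutive occupied bins *within one tiling*; runs alternating
between tilings are subsets of single-tiling runs and are not counted
separately.

The distribution of the longest run of occupied bins is approximated by
the Chen–Stein/Poisson method: the number of `k`-runs in a tiling of `b`
bins is approximately Poisson with rate

    λ(k) = b (1 − p) p^k ,

so `P(longest run < k) ≈ exp(−λ(k))`, and treating the two tilings as
independent

    P(M ≥ k) ≈ 1 − exp(−λ_W(k)) exp(−λ_O(k)),
    λ_W = T(1−p)p^k,  λ_O = (T−1)(1−p)p^k.

The occupancy vectors of the two tilings are in fact dependent (they are
driven by the same reads); the independence treatment and the absence of
boundary declumping terms are deliberate simplifications. Against the
exact longest-run probability for independent Bernoulli bins (a
transfer-matrix dynamic program used as a test oracle) the approximation
is within 0.05 absolute for `b ≤ 200`, `p ≤ 0.5`, `k = 2..8`, and the
survival curve is within 0.01 sup-distance of overlap-tiled simulation at
the 200 kb / 200 bp / 250–1000 read settings.

Known error structure, reproduced by the test suite and the `validate`
command rather than hidden:

* versus base-level (non-discretized) simulation the model overestimates
  by roughly one read-length: analytic `P(M ≥ k)` tracks simulated
  `P(M ≥ k−1)`; `validate` therefore flags divergence on the
  shift-adjusted sup-distance (default threshold 0.15);
* the approximation degrades with coverage and fails outright by ~4×
  depth (40000 reads on 2 Mb), where it underestimates maximum contig
  sizes severely;
* at `k = 1` the formula does not reduce to the trivial value 1 for
  `n ≥ 1`; it is computed as written, and all design criteria use
  `k ≥ 2`.

Analytic formulas use the real-valued bin counts `g/ℓ` and `g/ℓ − 1`
rather than floored integers: pool genome sizes are distribution
quantiles, and flooring would introduce step artifacts into the design
criteria. Simulators, which place discrete reads, always floor. The
probability is clamped to 0 when `k` exceeds `g/ℓ` (a contig cannot be
longer than its genome).

## Design criteria

All solvers find the smallest integer `N` whose criterion value reaches
the confidence `α`, by exponential bracketing followed by bisection; the
criteria are nondecreasing in `N` and comparisons use `≥` with no
floating-point slack, so the returned `N` is minimal (`criterion(N−1) <
α`). Reads are allocated to species by expectation: species `i` receives
`n_i = N π_i` reads where `π_i = a_i g_i / Σ_j a_j g_j` is its share of
the pooled DNA (`a_i` percentage abundance, `g_i` genome size). The
binomial spread of actual allocations around the expectation is ignored
in the criteria (the simulators do model it, multinomially).

* single-novel: `P₁(N/(S+1); g, ℓ, k) ≥ α` — only the novel genome must
  produce the contig.
* uniform-pool: `P₁(N/S)^S ≥ α` — assemblies are independent across
  species conditional on allocations.
* fixed-distributed-pool: `Π_i P₁(N π_i; g_i) ≥ α` over the
  quantile-assigned pool.
* stochastic-pool: `Σ_s w_s Π_i P₁(N π_i(s); g_i(s)) ≥ α`, the Poisson
  mixture over pool sizes; `s = 0` contributes a vacuous factor 1.

High-coverage cap: a species with expected coverage `n_i ℓ / g_i` at or
above a threshold (default 3.0×) contributes success probability exactly
1. The model is unreliable well before 4× and demonstrably understates
contig sizes there; without the cap, over-sampled abundant species would
dominate the product and inflate designs. The threshold is exposed as a
parameter (`coverage_cap`).

Poisson truncation: the mixture support is `0..q(1 − tol/2) + 2` with
`tol = 1e-9`, weights renormalized. The truncated tail carries below
`1e-9` of mass, negligible against the design tolerances.

## Pool construction

Genome sizes are the `i/(S+1)` quantiles (`i = 1..S`) of
Uniform(g_min, g_max); commonality-normalized abundances `x_i` are the
`i/(S+1)` quantiles of Pareto(scale 1, shape β), `x = (1−u)^(−1/β)`, and
percentage abundances are `a = x/Σx`. The `i/(S+1)` plotting position is
deliberate: for `S = 100, β = 3.5` it puts the most abundant species at
2.72% of the sample, a value consistent with observed viral metagenome
rank-abundance profiles, and it is what the calibration routine inverts.
(The alternative `(i−0.5)/S` convention would give ≈3.2% and is not
used.)

With no joint size–abundance model, ranks are paired "small-abundant"
(largest abundance on the smallest genome — the default, matching the
ecological pattern that large genomes are rare) or "large-abundant" (the
mirror image). Assigning abundances from a conditional distribution given
genome size would slot into `assemble_pool` naturally but is not
implemented.

Shape calibration solves `max(a) = target` for β by bracketed root
finding (the maximum abundance is strictly decreasing in β, from 1 toward
1/S), to 1e-9. For pool sizes where the target is unattainable
(`target ≤ 1/S`) abundances fall back to equal — relevant only in the far
tail of the Poisson mixture.

In the stochastic-pool criterion the shape is recalibrated at every pool
size `s` so the most abundant species stays at the target fraction
(default 2.5%). A fixed-shape mode is available instead
(`pareto_shape=`). The recalibrated mode is the default because it, and
not the fixed shape, reproduces the package's reference stochastic-pool
designs; for fixed-S designs the shape is given explicitly (3.5 for the
100-species examples; max abundance then 2.72%).

## Simulators

All simulators draw from a single numpy PCG64 generator seeded
explicitly; identical seed and parameters give bitwise-identical samples.

* base-level: starts uniform on the `g − ℓ + 1` positions that keep the
  read wholly inside the linear genome (no circularity); a contig is a
  maximal run of covered bases (abutting reads merge, a 1-base gap
  splits); the maximum contig is reported in read-lengths as a real
  number.
* wendl / overlap-tiled: reads dropped uniformly into `floor(g/ℓ)` or
  `2·floor(g/ℓ) − 1` bins; the maximum contig is the longest occupied-bin
  run (overlap mode: within each tiling separately, the larger taken).
* metagenome-minimax: per replicate, a multinomial split of the `N` reads
  over species (allocation probabilities `π`), base-level placement on
  each genome (sizes rounded to the nearest integer base), per-species
  maximum contigs, and the minimum across species — the quantity a
  pool-wide design guarantees. Species are processed in index order after
  the multinomial draw, fixing the replicate streams. A species receiving
  zero reads scores 0. The simulation reuses the fixed quantile pool
  across replicates rather than redrawing sizes/abundances; redrawing per
  replicate would mix pool-composition variance into the minimax
  distribution, which the design criterion does not model.

Summaries: right-continuous ECDFs and linearly interpolated sample
quantiles (numpy's default convention; the choice moves the reported 5%
and 95% minimax quantiles by under 0.05 read-lengths).

What the simulators do *not* model: sequence content, read errors,
overlap-detection thresholds, chimeras, paired ends, assembler behavior.
A real assembler needs a minimum detectable overlap, so base-level
"contigs" here (where a 1-base overlap merges) are themselves slightly
optimistic relative to practice. Passing tests show the analytic model
matches this idealized read-placement process, not any particular
assembler's output.

## Problem sizes and tolerances used in the checks

The test suite validates the run-rate against the exact DP at up to 200
bins; survival curves against 10⁴-replicate overlap simulations (sup
tolerance 0.04); the 4×-coverage breakdown at 200 base-level replicates
(the divergence there is ~0.6, far above noise); and the minimax medians
of the three stochastic viral designs at 100 replicates each against
their reference values within three bootstrap standard errors of the
median. Design read counts are asserted within 0.1% of their reference
values: several algebraically adjacent variants of the rate
formula were tested and the implemented one lands within a few
hundredths of a percent on all eighteen uniform-pool references while no
tested variant achieves exact integer agreement; the residual is
documented rather than absorbed into tuning.
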