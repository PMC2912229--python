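import numpy as np
import pytest


def exact_no_run_probability(bins: int, p: float, k: int) -> float:
    """Exact P(longest run of successes < k) for i.i.d. Bernoulli(p) trials.

    Transfer-matrix dynamic program over the current trailing run length
    (states 0..k-1); independent oracle for the Poisson run-rate
    approximation.
    """
    q = 1.0 - p
    state = np.zeros(k)
    state[0] = 1.0
    for _ in range(bins):
        new = np.empty(k)
        new[0] = q * state.sum()
        new[1:] = p * state[:-1]
        state = new
    return float(state.sum())


@pytest.fixture
def exact_no_run():
    return exact_no_run_probability


@pytest.fixture
def viral_pool():
    """The fixed 100-species viral quantile pool used throughout the examples."""
    from maxcontig import PoolDistributionSpec, materialize_pool

    spec = PoolDistributionSpec(
        size_min=50000, size_max=350000, species_count=100, pareto_shape=3.5
    )
    return materialize_pool(spec)
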