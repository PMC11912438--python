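import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def brute_force_edge_set(series, times=None):
    """Independent O(T^3) evaluation of the strict visibility criterion.

    For every pair i < j, checks every intermediate point directly against the
    chord; this is the correctness oracle for the graph construction.
    """
    x = np.asarray(series, dtype=float)
    t = (np.arange(1, x.size + 1, dtype=float) if times is None
         else np.asarray(times, dtype=float))
    edges = set()
    T = x.size
    for i in range(T - 1):
        for j in range(i + 1, T):
            if j == i + 1:
                edges.add((i, j))
                continue
            k = np.arange(i + 1, j)
            chord = x[j] + (x[i] - x[j]) * (t[j] - t[k]) / (t[j] - t[i])
            if np.all(x[k] < chord):
                edges.add((i, j))
    return edges


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort for pipeline-level tests (built once)."""
    from dmvg import CohortSpec, gen_cohort

    return gen_cohort(
        CohortSpec(n_variables=4, n_participants=3, n_trials=2,
                   trial_length=250, seed=42)
    )
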