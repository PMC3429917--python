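import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ldtscan import GeneticMap, MaxLodSample, simulate_population

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def unlinked_map_10():
    """10 mutually unlinked markers (one per chromosome): exchangeable columns."""
    return GeneticMap(
        tuple(f"m{i:02d}" for i in range(1, 11)),
        tuple(str(c) for c in range(1, 11)),
        np.full(10, 0.5),
    )


@pytest.fixture(scope="session")
def small_population(unlinked_map_10):
    """Null DH population on 10 unlinked markers."""
    return simulate_population(unlinked_map_10, n_obs=100, seed=11)


@pytest.fixture
def toy_sample_3m():
    """Hand-listed 60-draw sample over 3 markers, location counts (30, 15, 15).

    Conditional deltas: marker 1 -> 1..30, marker 2 -> 101..115,
    marker 3 -> 201..215 (distinct ranges so strata are unambiguous).
    p_lambda = (0.5, 0.25, 0.25), alpha = (2/3, 4/3, 4/3),
    validity upper bound = 3 * 0.25 = 0.75.
    """
    deltas = np.concatenate(
        [np.arange(1, 31), np.arange(101, 116), np.arange(201, 216)]
    ).astype(float)
    lams = np.concatenate([np.full(30, 1), np.full(15, 2), np.full(15, 3)])
    return MaxLodSample(deltas, lams, n_m=3)
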