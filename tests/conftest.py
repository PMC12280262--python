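import numpy as np
import pytest

from microcast import design as dz
from microcast import simulate as sim


@pytest.fixture(scope="session")
def pool():
    return dz.SpeciesPool.default()


@pytest.fixture(scope="session")
def calendar():
    return dz.SamplingCalendar.default()


@pytest.fixture(scope="session")
def compositions(pool):
    return dz.assemble_compositions(pool, n_per_level=5, seed=1)


@pytest.fixture(scope="session")
def bottles(compositions):
    return dz.build_bottle_grid(compositions)


@pytest.fixture(scope="session")
def default_params(pool):
    return sim.SimParams.default_for_pool(pool)


@pytest.fixture()
def quiet_params(pool):
    """Noise-free, event-free parameters for closed-form checks."""
    p = sim.SimParams.default_for_pool(pool)
    p.obs_noise_cv = 0.0
    p.env_noise_sd = 0.0
    p.oxygen_noise_sd = 0.0
    p.count_volumes = None
    p.missingness = {}
    p.immigration_dose = 0.0
    return p


def logistic_map(n: int, r: float = 3.8, x0: float = 0.123) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    for i in range(1, n):
        x[i] = r * x[i - 1] * (1.0 - x[i - 1])
    return x
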