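import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import plastnet as pn

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: single shared seed for every seeded reference run in the suite
REFERENCE_SEED = 1


@pytest.fixture(scope="session")
def pair_trace():
    """Two coupled neurons, 600 ms (coupling from 400 ms)."""
    return pn.run_simulation(pn.make_fixture("pair", seed=REFERENCE_SEED)["config"])


@pytest.fixture(scope="session")
def lattice16_trace():
    """Seeded 4x4 torus scenario, 1000 ms (coupling from 400 ms)."""
    return pn.run_simulation(pn.make_fixture("lattice16", seed=REFERENCE_SEED)["config"])


@pytest.fixture(scope="session")
def lattice16_partitions(lattice16_trace):
    import plastnet.communities as communities

    return communities.window_partitions(lattice16_trace)


def brute_force_min_image_distance(p, q, global_l):
    """Distance oracle: explicit minimum over the 9 periodic images."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    best = np.inf
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            shift = np.array([sx, sy]) * global_l
            best = min(best, float(np.linalg.norm(p - (q + shift))))
    return best
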