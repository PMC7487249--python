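import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import polygrowth as pg

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def fast_pso():
    """Small deterministic swarm budget for 2-parameter problems."""
    return pg.PsoSettings(n_particles=15, n_iters=60, seed=11)


@pytest.fixture
def tiny_pso():
    """Minimal swarm budget for the heavier nested (gengamma) problems."""
    return pg.PsoSettings(n_particles=12, n_iters=40, seed=11)


@pytest.fixture
def larch_al():
    return pg.reference_models()["larch_AL"]


@pytest.fixture
def cypress_pg():
    return pg.reference_models()["cypress_PG"]
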