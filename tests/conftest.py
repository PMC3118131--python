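import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hapcore.simulate import DiseaseModel, SimConfig, make_fixture_pool, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pool25():
    """Standard fixture pool: 15 haplotypes, 10 cores at 0.9 mass, p = 0.25."""
    return make_fixture_pool(target_p=0.25, seed=7)


@pytest.fixture(scope="session")
def null_dataset(pool25):
    """A null-simulated dataset of 80 families from the standard pool."""
    cfg = SimConfig(
        n_families=80,
        pools=pool25,
        model=DiseaseModel.null(p=0.25),
        seed=3,
        sibship_seed=3,
    )
    fams, truth = simulate_dataset(cfg)
    return fams, truth


@pytest.fixture(scope="session")
def disease_dataset(pool25):
    """An additive r=3, p=0.25 dataset of 120 families."""
    cfg = SimConfig(
        n_families=120,
        pools=pool25,
        model=DiseaseModel.from_mode("additive", 3.0, 0.25),
        seed=4,
        sibship_seed=4,
    )
    fams, truth = simulate_dataset(cfg)
    return fams, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
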