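import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import parcelbrain as pb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_atlas() -> pb.AtlasLabelMap:
    """A 40-parcel atlas on a small grid (20/12/8 per compartment)."""
    return pb.build_default_atlas(
        grid_shape=(12, 12, 12),
        seed=7,
        compartment_counts={"cortical": 20, "subcortical": 12, "cerebellar": 8},
    )


@pytest.fixture(scope="session")
def small_config() -> pb.SimulationConfig:
    """Desk-scale simulation config used by most unit tests."""
    return pb.SimulationConfig(
        n_reference=300,
        n_parcels=40,
        n_study_per_cell={"HC": 20, "MCI": 40, "AD": 15},
        seed=123,
    )


@pytest.fixture(scope="session")
def study_data(small_config):
    return pb.generate_study_cohort(small_config)


@pytest.fixture(scope="session")
def reference_data(small_config):
    return pb.generate_reference_cohort(small_config)


def rng_of(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
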