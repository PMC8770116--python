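import pytest
from hypothesis import HealthCheck, settings

from migrisk import (
    SyntheticConfig,
    default_archetypes,
    default_material_library,
    generate_synthetic_dataset,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def materials():
    return default_material_library()


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def synth_dataset(materials, archetypes):
    """The default synthetic harmonized dataset (437 rows, seed 42)."""
    return generate_synthetic_dataset(
        SyntheticConfig(seed=42), materials=materials, archetypes=archetypes
    )


@pytest.fixture(scope="session")
def noiseless_dataset(materials, archetypes):
    """Noise-free synthetic dataset: observed rates equal mechanistic truth."""
    return generate_synthetic_dataset(
        SyntheticConfig(n_observations=120, seed=7, log10_noise_sd=0.0),
        materials=materials,
        archetypes=archetypes,
    )
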