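import numpy as np
import pytest

from opporscreen import CohortSpec, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast phantom spec shared by the imaging tests."""
    return PhantomSpec(
        levels=("L1", "L2"),
        body_extent_mm=(26.0, 22.0, 20.0),
        shell_thickness_mm=3.0,
        trabecular_density=100.0,
        cortical_density=400.0,
        noise_sd=0.0,
        spacing_mm=(1.0, 1.0, 1.0),
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def table1_cohort():
    """One cohort drawn at the published group parameters (44/148)."""
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
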