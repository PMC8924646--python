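import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def cohort_and_visits():
    """One moderately sized simulated cohort shared across tests."""
    from gmnet.synthetic_data import CohortSimSpec, generate_cohort

    return generate_cohort(CohortSimSpec(n_subjects=600, seed=11))


@pytest.fixture(scope="session")
def planted_volume_nodes():
    """A planted-structure volume with its extracted cube nodes."""
    from gmnet.network_construction import extract_cubes
    from gmnet.synthetic_data import VolumeSimSpec, generate_structured_volume

    spec = VolumeSimSpec(shape=(18, 18, 18), n_patterns=3, members_per_pattern=8, seed=5)
    vol = generate_structured_volume(spec)
    return spec, vol, extract_cubes(vol)
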