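import pytest

from contactsurf import generate_sphere_points


@pytest.fixture(scope="session")
def lattice():
    """Default-resolution sampling lattice shared across the suite."""
    return generate_sphere_points(2000)


@pytest.fixture(scope="session")
def coarse_lattice():
    """Cheaper lattice for property tests that only need topology."""
    return generate_sphere_points(500)
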