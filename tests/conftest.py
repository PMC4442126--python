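import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_lattice():
    from afpice.lattice import LatticeSpec, build_ice_lattice

    return build_ice_lattice(LatticeSpec(n_a=2, n_b=2, n_c=2))


@pytest.fixture(scope="session")
def unit_cell():
    from afpice.lattice import LatticeSpec, build_ice_lattice

    return build_ice_lattice(LatticeSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
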