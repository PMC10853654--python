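import numpy as np
import pytest

import epimeg
from epimeg.fitting import LeadFieldGrid


@pytest.fixture(scope="session")
def sphere():
    return epimeg.SphereModel()


@pytest.fixture(scope="session")
def array():
    return epimeg.generate_sensor_array(102, 110.0, seed=1)


@pytest.fixture(scope="session")
def grid(array, sphere):
    return LeadFieldGrid.build(array, sphere)


@pytest.fixture(scope="session")
def parcellation():
    return epimeg.generate_parcellation()


def random_tangential_dipole(rng, r_min=20.0, r_max=78.0, amplitude=250.0):
    """A random tangential dipole inside the default conductor."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    pos = rng.uniform(r_min, r_max) * u
    mom = rng.normal(size=3)
    mom -= (mom @ u) * u
    mom *= amplitude / np.linalg.norm(mom)
    return epimeg.CurrentDipole(position=pos, moment=mom)
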