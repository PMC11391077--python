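import numpy as np
import pytest

import biomefusion as bf


@pytest.fixture(scope="session")
def scheme():
    return bf.default_scheme()


@pytest.fixture(scope="session")
def transforms():
    return bf.default_transforms()


@pytest.fixture
def small_geometry():
    """10x8 grid at 1 degree over a tropical window."""
    return bf.GridGeometry(lon_min=-70, lon_max=-60, lat_min=-5, lat_max=3, resolution=1.0)


@pytest.fixture
def tropical_values():
    """A six-tuple safely inside the tropical humid forest box."""
    return {
        "fpc": 0.8,
        "height": 15.0,
        "evergreen": 0.8,
        "tropical": 0.7,
        "temperate": 0.2,
        "gdd": 6000.0,
    }


def sample_valid_tuples(rng, n):
    """Uniform samples over the attainable variable space."""
    return {
        "fpc": rng.uniform(0, 1, n),
        "height": rng.uniform(0, 130, n),
        "evergreen": rng.uniform(0, 1, n),
        "tropical": rng.uniform(0, 1, n),
        "temperate": rng.uniform(0, 1, n),
        "gdd": rng.uniform(0, 10000, n),
    }
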