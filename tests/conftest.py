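import numpy as np
import pytest

from migpatterns import (
    GeoPopulation,
    assemble_pattern,
    delaunay_triangulate,
    load_fixture,
)


@pytest.fixture(scope="session")
def sumba():
    return load_fixture()


@pytest.fixture(scope="session")
def sumba_complex(sumba):
    return delaunay_triangulate(sumba.populations)


@pytest.fixture(scope="session")
def sumba_pattern(sumba):
    return assemble_pattern(sumba.populations, sumba.weights)


@pytest.fixture(scope="session")
def tetra_populations():
    """Four populations at the vertices of a near-regular tetrahedron."""
    return [
        GeoPopulation("A", 0.0, 89.0),
        GeoPopulation("B", 0.0, -19.47),
        GeoPopulation("C", 120.0, -19.47),
        GeoPopulation("D", -120.0, -19.47),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
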