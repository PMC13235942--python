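import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import cleftpnp as cp

hyp_settings.register_profile("suite", derandomize=True, max_examples=40,
                              deadline=None)
hyp_settings.load_profile("suite")


@pytest.fixture(scope="session")
def constants():
    return cp.PhysicalConstants()


@pytest.fixture(scope="session")
def species():
    return cp.default_species()


@pytest.fixture(scope="session")
def geometry():
    return cp.Geometry()


@pytest.fixture(scope="session")
def ics():
    return cp.InitialConditions()


@pytest.fixture(scope="session")
def coarse_mesh(geometry):
    return cp.build_mesh(geometry, cp.MeshResolution.coarse())


@pytest.fixture(scope="session")
def synapse_state(coarse_mesh, ics):
    return cp.initialize_state(coarse_mesh, ics)


def make_closed_box(n=6, length=60.0):
    """Small closed cubic box of extracellular cells for conservation tests."""
    ex = np.linspace(0.0, length, n + 1)
    region = np.full((n, n, n), cp.Region.EXTRACELLULAR, dtype=np.int8)
    return cp.Mesh(ex=ex, ey=ex.copy(), ez=ex.copy(), region=region)


@pytest.fixture()
def closed_box():
    return make_closed_box()
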