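import sys
from pathlib import Path

import numpy as np
import pytest
from shapely.geometry import Point

sys.path.insert(0, str(Path(__file__).parent))

from csfhydro.anatomy import CrossSection, StationParams
from csfhydro.fluid import CSF
from csfhydro.synthetic import make_flow_waveform

PIPE_RADIUS = 5.0       # mm
ANNULUS_RO = 8.0        # mm
ANNULUS_RI = 4.0        # mm


@pytest.fixture(scope="session")
def fluid():
    return CSF


@pytest.fixture(scope="session")
def pipe_section():
    circle = Point(0, 0).buffer(PIPE_RADIUS, quad_segs=128)
    return CrossSection(station="pipe",
                        params=StationParams("pipe", PIPE_RADIUS, 0.01),
                        lumen=circle)


@pytest.fixture(scope="session")
def annulus_section():
    outer = Point(0, 0).buffer(ANNULUS_RO, quad_segs=128)
    inner = Point(0, 0).buffer(ANNULUS_RI, quad_segs=128)
    return CrossSection(station="annulus",
                        params=StationParams("annulus", ANNULUS_RO, ANNULUS_RI),
                        lumen=outer.difference(inner))


@pytest.fixture(scope="session")
def default_waveform():
    return make_flow_waveform()


@pytest.fixture(scope="session")
def pipe_mesh(pipe_section):
    from csfhydro.solver import mesh_section
    return mesh_section(pipe_section)


@pytest.fixture(scope="session")
def annulus_mesh(annulus_section):
    from csfhydro.solver import mesh_section
    return mesh_section(annulus_section)


@pytest.fixture(scope="session")
def geometry_pair():
    """Default nine-station geometry with and without NRDL."""
    from csfhydro.anatomy import build_geometry
    return build_geometry(with_nrdl=True), build_geometry(with_nrdl=False)


@pytest.fixture(scope="session")
def solved_pair(geometry_pair, default_waveform, fluid):
    """Medium-mesh solves of the with/without-NRDL cases (shared: costly)."""
    from csfhydro.solver import solve_geometry
    geo_w, geo_wo = geometry_pair
    sol_w = solve_geometry(geo_w, fluid, default_waveform)
    sol_wo = solve_geometry(geo_wo, fluid, default_waveform)
    return sol_w, sol_wo


def rel_l2(a, b):
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
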