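"""Shared fixtures: small analytic meshes and session-scoped synthetic
anatomy (femur generation is the expensive part, so models are built once
per session)."""

import numpy as np
import pytest
import trimesh

from platefit.mesh_core import TriangleMesh
from platefit.synthetic_anatomy import (
    FemurParams,
    PlateParams,
    make_femur,
    make_plate,
)


@pytest.fixture(scope="session")
def unit_sphere() -> TriangleMesh:
    m = trimesh.creation.icosphere(subdivisions=3)
    return TriangleMesh.from_arrays(m.vertices, m.faces, name="unit_sphere")


@pytest.fixture(scope="session")
def cylinder() -> TriangleMesh:
    m = trimesh.creation.cylinder(radius=10.0, height=40.0, sections=128)
    return TriangleMesh.from_arrays(m.vertices, m.faces, name="cylinder")


@pytest.fixture(scope="session")
def default_femur():
    return make_femur(FemurParams())


@pytest.fixture(scope="session")
def matched_femur():
    """A femur whose bow radius equals the default plate bow radius."""
    return make_femur(FemurParams(r_bow=940.0, diaphysis_length=365.0))


@pytest.fixture(scope="session")
def plate11():
    return make_plate(PlateParams(holes=11))


@pytest.fixture(scope="session")
def plate_set():
    from platefit.synthetic_anatomy import make_plate_set
    return make_plate_set()
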