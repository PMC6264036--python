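import numpy as np
import pytest

from flipdg.dg_core import DGSpace
from flipdg.mesh_geometry import (
    Circle,
    SyntheticGeometrySpec,
    TriangleMesh,
    build_synthetic_cell,
    unit_square_mesh,
)


@pytest.fixture(scope="session")
def two_region_mesh():
    """Concentric cell/nucleus discs, no aggregates."""
    spec = SyntheticGeometrySpec(cell=Circle((0, 0), 15.0), nucleus=Circle((0, 0), 6.0), h=1.5)
    return build_synthetic_cell(spec)


@pytest.fixture(scope="session")
def cell_mesh():
    """Small full-featured cell: nucleus, bleach disc, one aggregate."""
    spec = SyntheticGeometrySpec(
        cell=Circle((0, 0), 10.0),
        nucleus=Circle((-2.5, 0), 4.0),
        aggregates=[Circle((4.5, 3.0), 1.8)],
        bleach=Circle((-2.5, 0), 1.2),
        h=1.5,
    )
    return build_synthetic_cell(spec)


@pytest.fixture(scope="session")
def cell_space(cell_mesh):
    return DGSpace(cell_mesh)


@pytest.fixture(scope="session")
def square_space():
    return DGSpace(unit_square_mesh(4))


def _two_triangle_interface_mesh(tag_left: int, tag_right: int) -> TriangleMesh:
    """Unit square split along the diagonal (0,0)-(1,1) into two compartments."""
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    tags = np.array([tag_left, tag_right])
    return TriangleMesh(verts, tris, tags, np.zeros(2, dtype=bool))


@pytest.fixture(scope="session")
def make_interface_mesh():
    """Factory for a two-triangle mesh with a single internal interface edge."""
    return _two_triangle_interface_mesh
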