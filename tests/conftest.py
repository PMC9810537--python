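import numpy as np
import pytest
import trimesh

from lvvol.geometry import Contour2D
from lvvol.synthetic import ParaboloidSpec, ViewConfig, view_pair


def semicircle_contour(radius=30.0, n=201):
    """Open semicircular tracing: flat basal chord on top, apex at the bottom.

    Runs from basal corner (-r, 0) through the apex (0, -r) to (r, 0).
    """
    theta = np.linspace(np.pi, 2.0 * np.pi, n)
    pts = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return Contour2D(pts)


def pentagon_contour(width=30.0, height=60.0, apex_drop=20.0):
    """Rectangle with a V apex: constant chord width over the straight part."""
    w = width / 2.0
    left = np.column_stack([np.full(30, -w), np.linspace(height, 0, 30)])
    tip = np.array([[0.0, -apex_drop]])
    right = np.column_stack([np.full(30, w), np.linspace(0, height, 30)])
    return Contour2D(np.vstack([left, tip, right]))


@pytest.fixture(scope="session")
def ideal_view():
    return ViewConfig(orientation_deg=0.0, viewing_angle_deg=90.0)


@pytest.fixture(scope="session")
def slanted_spec(ideal_view):
    """Default workbench phantom: mu=1.1, both views slanted 7 degrees."""
    return ParaboloidSpec.for_view_slant(7.0, ideal_view, eccentricity=1.1)


@pytest.fixture(scope="session")
def slanted_pair(slanted_spec, ideal_view):
    return view_pair(slanted_spec, ideal_view)


@pytest.fixture(scope="session")
def unslanted_spec():
    return ParaboloidSpec(eccentricity=1.1)


@pytest.fixture()
def cube_ply(tmp_path):
    path = tmp_path / "cube.ply"
    trimesh.creation.box(extents=(10.0, 10.0, 10.0)).export(path)
    return path


@pytest.fixture()
def icosphere_obj(tmp_path):
    path = tmp_path / "sphere.obj"
    trimesh.creation.icosphere(subdivisions=4, radius=20.0).export(path)
    return path


@pytest.fixture()
def open_mesh_ply(tmp_path):
    """A basally truncated (uncapped) surface: deliberately not closed."""
    from lvvol.synthetic import make_paraboloid

    spec = ParaboloidSpec(n_boundary=64, n_rings=16)
    mesh = make_paraboloid(spec)
    cap_center = len(mesh.vertices) - 1
    keep = ~np.any(mesh.faces == cap_center, axis=1)
    open_mesh = trimesh.Trimesh(vertices=mesh.vertices,
                                faces=mesh.faces[keep], process=False)
    path = tmp_path / "open.ply"
    open_mesh.export(path)
    return path
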