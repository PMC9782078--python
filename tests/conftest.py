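import numpy as np
import pytest

from ctcfi.phantom import (PolypSpec, make_colon_phantom, make_tube_mesh,
                           straight_tube_spec, tube_bump_annotations)
from ctcfi.surface import Centerline, compute_vertex_curvature


@pytest.fixture(scope="session")
def straight_phantom():
    """64^3 straight-tube phantom (radius 10 mm) with ground truth."""
    spec = straight_tube_spec((64, 64, 64), lumen_radius_mm=10.0, seed=11)
    return make_colon_phantom(spec)


@pytest.fixture(scope="session")
def curved_phantom():
    from ctcfi.phantom import PhantomSpec

    spec = PhantomSpec(grid_shape=(80, 64, 64), lumen_radius_mm=9.0, seed=7)
    return make_colon_phantom(spec)


@pytest.fixture(scope="session")
def tube_mesh_with_bump():
    """80 mm tube of radius 10 with a 3 mm bump at azimuth 90, mid-arc."""
    length, radius = 80.0, 10.0
    bump = PolypSpec(arc_position=0.5, azimuth_deg=90.0, radius_mm=3.0)
    mesh = make_tube_mesh(length, radius, [bump], n_theta=96, axial_step_mm=1.0)
    mesh = compute_vertex_curvature(mesh)
    annotations = tube_bump_annotations(length, radius, [bump])
    axis = np.column_stack([np.linspace(0, length, 41), np.zeros(41), np.zeros(41)])
    return mesh, Centerline(points=axis), annotations, (length, radius)


@pytest.fixture(scope="session")
def plain_tube_mesh():
    mesh = make_tube_mesh(80.0, 10.0, [], n_theta=96, axial_step_mm=1.0)
    return compute_vertex_curvature(mesh)
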