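"""Shared fixtures: small templates, analytic centerlines, cylinder meshes."""

import numpy as np
import pytest

import fenplan as fp
from fenplan import meshing, parameterize


@pytest.fixture(scope="session")
def uniform_template():
    return fp.make_template({
        "name": "test-uniform-30", "length": 100, "D_prox": 30, "D_dist": 30,
        "amplitude": 12, "wire": 0.5, "peaks": 8,
        "positions": [10, 30, 50, 70, 90],
    })


@pytest.fixture(scope="session")
def tapered_template():
    return fp.make_template({
        "name": "test-tapered", "length": 100, "D_prox": 34, "D_dist": 30,
        "amplitude": 12, "wire": 0.5, "peaks": 8,
        "positions": [10, 30, 50, 70, 90],
    })


@pytest.fixture(scope="session")
def straight_centerline():
    """Analytic straight centerline on the z axis, 30 mm lumen, descending."""
    z = np.linspace(200.0, 0.0, 60)
    pts = np.column_stack([np.full_like(z, 50.0), np.full_like(z, 50.0), z])
    return fp.centerline_from_polyline(pts, 30.0, smoothing=0.0)


@pytest.fixture(scope="session")
def cylinder_mesh(straight_centerline):
    """Straight cylinder D=30, L=100, n_circ=96, lofted from station 20."""
    return meshing.loft_mesh(straight_centerline.spline, 30.0, 20.0, 100.0,
                             n_axial=101, n_circ=96)


@pytest.fixture(scope="session")
def cylinder_param(cylinder_mesh):
    L = parameterize.cotangent_laplacian(cylinder_mesh)
    return parameterize.embed_rectangle(cylinder_mesh, L, (np.pi * 30.0, 100.0))


@pytest.fixture(scope="session")
def straight_case():
    return fp.generate_case("straight", 0.0, seed=1)


@pytest.fixture(scope="session")
def straight_plan(straight_case):
    model = fp.FenestrationPlanner.from_synthetic(straight_case)
    return model.fit()
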