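import numpy as np
import pytest
import trimesh

import petromap as pm
from petromap.phantom import AirCellSpec
from petromap.thickness import CLTParams, GridSpec, compute_clt, compute_ddvs, project_grid_local


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def icosphere():
    s = trimesh.creation.icosphere(subdivisions=3)
    return pm.TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces), name="icosphere")


@pytest.fixture(scope="session")
def unit_cube():
    b = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return pm.TriangleMesh(np.asarray(b.vertices), np.asarray(b.faces), name="cube")


def random_triangle_soup(rng, n_triangles=50, scale=10.0):
    """Well-conditioned random triangles scattered in a cube."""
    centers = rng.uniform(-scale, scale, size=(n_triangles, 3))
    tris = centers[:, None, :] + rng.normal(scale=1.5, size=(n_triangles, 3, 3))
    verts = tris.reshape(-1, 3)
    faces = np.arange(len(verts)).reshape(-1, 3)
    return pm.TriangleMesh(verts, faces, name="soup")


@pytest.fixture
def triangle_soup(rng):
    return random_triangle_soup(rng)


@pytest.fixture(scope="session")
def slab_mesh():
    """One-sided flat square at z = 0 covering [-1, 3]^2."""
    v = np.array([[-1, -1, 0], [3, -1, 0], [3, 3, 0], [-1, 3, 0]], dtype=float)
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return pm.TriangleMesh(v, f, name="slab")


@pytest.fixture(scope="session")
def tiny_phantom():
    """~100-face constant phantom for brute-force oracle comparisons."""
    cfg = pm.PhantomConfig(
        grid_extent=4.0, mesh_resolution=2.0, dome_amplitude=0.5, dome_sigma=10.0,
        base_thickness_field=pm.ScalarField2D(a=1.5),
        dura_depth_field=pm.ScalarField2D(a=3.0),
        seed=7,
    )
    return cfg, pm.generate_phantom(cfg)


@pytest.fixture(scope="session")
def flat_phantom():
    """Constant thickness 2 mm, dura at 5 mm, no air cells."""
    cfg = pm.PhantomConfig(
        grid_extent=30.0, mesh_resolution=1.0,
        base_thickness_field=pm.ScalarField2D(a=2.0),
        dura_depth_field=pm.ScalarField2D(a=5.0),
        seed=1,
    )
    return cfg, pm.generate_phantom(cfg)


@pytest.fixture(scope="session")
def cell_phantom():
    """Phantom with air cells and a sinus ridge."""
    cfg = pm.PhantomConfig(
        grid_extent=35.0, mesh_resolution=1.0, seed=5,
        base_thickness_field=pm.ScalarField2D(kind="linear", a=2.5, b=0.02),
        dura_depth_field=pm.ScalarField2D(a=6.0),
        air_cells=AirCellSpec(count=12, radius_range=(0.4, 0.8), depth_range=(0.8, 1.6)),
        sinus_tube=pm.SinusTube(p0=(-18.0, -18.0), p1=(18.0, 18.0), depth=4.5, radius=1.5),
    )
    return cfg, pm.generate_phantom(cfg)


@pytest.fixture(scope="session")
def flat_analysis(flat_phantom):
    """Projected + measured samples on the flat phantom."""
    _, (bone, dura, truth) = flat_phantom
    grid = GridSpec(spacing=1.0, extent=(-20, 20, -20, 20))
    samples = project_grid_local(bone, grid)
    compute_clt(samples, bone, CLTParams())
    compute_ddvs(samples, dura)
    return grid, samples, truth


@pytest.fixture(scope="session")
def cell_analysis(cell_phantom):
    _, (bone, dura, truth) = cell_phantom
    grid = GridSpec(spacing=1.0, extent=(-22, 22, -22, 22))
    samples = project_grid_local(bone, grid)
    compute_clt(samples, bone, CLTParams())
    compute_ddvs(samples, dura)
    return grid, samples, truth
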