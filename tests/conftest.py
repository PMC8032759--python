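import numpy as np
import pytest
import trimesh

import corticofold as cf


@pytest.fixture(scope="session")
def unit_sphere_surface():
    return trimesh.creation.icosphere(subdivisions=3, radius=1.0)


@pytest.fixture(scope="session")
def cylinder_surface():
    """Open cylinder of radius 1 (caps excluded), z in [0, 4]."""
    n_theta, n_z = 48, 24
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(0.0, 4.0, n_z)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    verts = np.stack([np.cos(tt).ravel(), np.sin(tt).ravel(), zz.ravel()], axis=1)

    def vid(i, j):
        return (i % n_theta) * n_z + j

    faces = []
    for i in range(n_theta):
        for j in range(n_z - 1):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append([a, b, c])
            faces.append([a, c, d])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


@pytest.fixture(scope="session")
def small_ellipsoid_mesh():
    """Coarse reference-ellipsoid tet mesh (mm units)."""
    return cf.build_ellipsoid_tetmesh(cf.EllipsoidSpec.reference(), 1e3, seed=7)


@pytest.fixture(scope="session")
def tiny_ball_mesh():
    """~50-100 tet unit ball for force-gradient oracles."""
    return cf.build_ellipsoid_tetmesh(cf.EllipsoidSpec(1.0, 1.0, 1.0), 6e4, seed=3)


@pytest.fixture(scope="session")
def single_tet_mesh():
    verts = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 1]])
    return cf.TetMesh(vertices=verts, tets=np.array([[0, 1, 2, 3]]), units="mm")
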