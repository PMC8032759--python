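import numpy as np
import pytest

import corticofold as cf
from corticofold import simulate as sim
from corticofold.growth import growth_tensor


@pytest.fixture(scope="module")
def ball_state(tiny_ball_mesh):
    normed, _ = cf.normalize(tiny_ball_mesh)
    cfg = sim.SimConfig(thickness_mm=0.3)
    state = sim.initialize(normed, cfg, sim.Material(),
                           thickness_normalized=0.15)
    return state, cfg


class TestInitialize:
    def test_rest_state_has_zero_forces(self, ball_state):
        state, _ = ball_state
        state.g_tet = np.ones(state.mesh.n_tets)
        f = sim.elastic_nodal_forces(state, sim.Material())
        assert np.abs(f).max() < 1e-10
        assert state.elastic_energy == pytest.approx(0.0, abs=1e-12)

    def test_normals_are_unit(self, ball_state):
        state, _ = ball_state
        np.testing.assert_allclose(
            np.linalg.norm(state.normals, axis=1), 1.0, atol=1e-9)

    def test_surface_tets_shallow_interior_deep(self, ball_state):
        state, _ = ball_state
        nb = state.mesh.is_boundary_vertex[state.mesh.tets].sum(axis=1)
        all_boundary = nb == 4
        if all_boundary.any():
            assert state.y_tet[all_boundary].max() == pytest.approx(0.0, abs=1e-9)
        assert state.y_tet.max() > 0.1

    def test_requires_normalized_mesh(self, tiny_ball_mesh):
        with pytest.raises(ValueError, match="normalized"):
            sim.initialize(tiny_ball_mesh, sim.SimConfig(), sim.Material())


class TestDeformationGradient:
    def test_identity_at_rest(self):
        rng = np.random.default_rng(0)
        ahat = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        F = sim.deformation_gradient(ahat, np.eye(3), ahat)
        np.testing.assert_allclose(F, np.eye(3), atol=1e-12)

    def test_growth_removed_from_reference(self):
        rng = np.random.default_rng(1)
        ahat = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        G = np.diag([2.0, 2.0, 1.0])
        F = sim.deformation_gradient(ahat, G, ahat)
        # A equals the ungrown element: relative to the grown reference the
        # element is compressed tangentially, det F = 1/det(G) = 1/4
        assert np.linalg.det(F) == pytest.approx(0.25, rel=1e-9)

    def test_rotation_of_grown_reference_is_stress_free(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        ahat = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        n = rng.standard_normal(3)
        n /= np.linalg.norm(n)
        G = growth_tensor(1.7, n)
        R = Rotation.from_rotvec([0.4, -0.2, 0.9]).as_matrix()
        F = sim.deformation_gradient(R @ G @ ahat, G, ahat)
        np.testing.assert_allclose(F, R, atol=1e-10)

    def test_singular_reference_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            sim.deformation_gradient(np.eye(3), np.eye(3), np.zeros((3, 3)))


class TestElasticForces:
    def test_forces_sum_to_zero(self, ball_state):
        state, _ = ball_state
        rng = np.random.default_rng(3)
        state.g_tet = 1.0 + 0.4 * rng.random(state.mesh.n_tets)
        pos0 = state.pos.copy()
        state.pos = pos0 + 0.01 * rng.standard_normal(pos0.shape)
        f = sim.elastic_nodal_forces(state, sim.Material())
        state.pos = pos0
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)

    def test_zero_torque_free_boundary(self, ball_state):
        state, _ = ball_state
        rng = np.random.default_rng(4)
        state.g_tet = 1.0 + 0.4 * rng.random(state.mesh.n_tets)
        pos0 = state.pos.copy()
        state.pos = pos0 + 0.01 * rng.standard_normal(pos0.shape)
        f = sim.elastic_nodal_forces(state, sim.Material())
        torque = np.cross(state.pos, f).sum(axis=0)
        state.pos = pos0
        np.testing.assert_allclose(torque, 0.0, atol=1e-10)

    def test_matches_finite_difference_gradient(self, ball_state):
        state, _ = ball_state
        mat = sim.Material()
        rng = np.random.default_rng(5)
        state.g_tet = 1.0 + 0.5 * rng.random(state.mesh.n_tets)
        pos0 = state.pos.copy()
        state.pos = pos0 + 0.02 * rng.standard_normal(pos0.shape)
        base = state.pos.copy()
        f = sim.elastic_nodal_forces(state, mat)
        eps = 1e-6
        for _ in range(10):
            i = rng.integers(state.mesh.n_vertices)
            j = rng.integers(3)
            state.pos = base.copy()
            state.pos[i, j] += eps
            sim.elastic_nodal_forces(state, mat)
            e_plus = state.elastic_energy
            state.pos = base.copy()
            state.pos[i, j] -= eps
            sim.elastic_nodal_forces(state, mat)
            e_minus = state.elastic_energy
            fd = -(e_plus - e_minus) / (2 * eps)
            assert f[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-10)
        state.pos = pos0

    def test_rigid_rotation_gives_zero_force(self, ball_state):
        from scipy.spatial.transform import Rotation

        state, _ = ball_state
        state.g_tet = np.ones(state.mesh.n_tets)
        R = Rotation.from_rotvec([0.3, 0.2, 0.1]).as_matrix()
        pos0 = state.pos.copy()
        state.pos = state.material_pos @ R.T
        f = sim.elastic_nodal_forces(state, sim.Material())
        state.pos = pos0
        assert np.abs(f).max() < 1e-8

    def test_strict_mode_raises_on_inversion(self, ball_state):
        state, _ = ball_state
        state.g_tet = np.ones(state.mesh.n_tets)
        pos0 = state.pos.copy()
        squashed = state.pos.copy()
        squashed[:, 2] *= -0.5  # reflect: every element inverts
        state.pos = squashed
        with pytest.raises(sim.ElementInversionError):
            sim.elastic_nodal_forces(state, sim.Material())
        state.pos = pos0


class TestContact:
    def test_convex_rest_state_has_no_contacts(self, ball_state):
        state, cfg = ball_state
        thr = 0.5 * state.spacing
        f = sim.contact_nodal_forces(state, thr, 5.0)
        assert np.abs(f).max() == 0.0
        assert state.n_contacts == 0

    def test_penalty_force_on_synthetic_pair(self):
        # a boundary vertex of one tet hovering above a triangle of another
        verts = np.array([
            [0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0.33, 0.33, -1.0],  # lower
            [0.3, 0.3, 0.1], [1.3, 0.3, 0.1], [0.3, 1.3, 0.1], [0.6, 0.6, 1.1],
        ])
        mesh = cf.TetMesh(vertices=verts, tets=np.array([[0, 2, 1, 3],
                                                         [4, 5, 6, 7]]),
                          units="normalized")
        cfg = sim.SimConfig()
        state = sim.initialize(mesh, cfg, sim.Material(),
                               thickness_normalized=0.1)
        threshold, stiffness = 0.2, 7.0
        # these two tets are intentionally close in the material frame:
        # disable the intrinsic-neighbour exclusion for the hand evaluation
        pairs = sim.contact_pairs(state, threshold, exclusion_factor=0.0)
        f = sim.contact_nodal_forces(state, threshold, stiffness, pairs=pairs)
        # vertex 4 sits 0.1 above triangle (0,1,2): penalty k*(0.2-0.1)
        assert np.linalg.norm(f[4]) == pytest.approx(stiffness * 0.1, rel=1e-9)
        assert f[4][2] > 0
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12)

    def test_force_continuous_at_threshold(self):
        verts = np.array([
            [0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0.33, 0.33, -1.0],
            [0.3, 0.3, 0.2], [1.3, 0.3, 0.2], [0.3, 1.3, 0.2], [0.6, 0.6, 1.2],
        ])
        mesh = cf.TetMesh(vertices=verts, tets=np.array([[0, 2, 1, 3],
                                                         [4, 5, 6, 7]]),
                          units="normalized")
        state = sim.initialize(mesh, sim.SimConfig(), sim.Material(),
                               thickness_normalized=0.1)
        f = sim.contact_nodal_forces(state, 0.2, 7.0)
        assert np.abs(f).max() < 1e-12


class TestStep:
    def test_timestep_rule(self):
        cfg = sim.SimConfig()
        assert cfg.timestep(1.0, sim.Material(mu=0.2, K=1.0, rho=1.0)) == (
            pytest.approx(0.05))

    def test_damped_relaxation_dissipates_energy(self, tiny_ball_mesh):
        normed, _ = cf.normalize(tiny_ball_mesh)
        cfg = sim.SimConfig(thickness_mm=0.3, damping=30.0)
        mat = sim.Material()
        state = sim.initialize(normed, cfg, mat, thickness_normalized=0.15)
        rng = np.random.default_rng(0)
        state.pos += 0.02 * rng.standard_normal(state.pos.shape)
        # growth off: pure relaxation toward the rest state
        law = cf.GrowthLaw.logistic(b=50.0, c=10.0)  # alpha ~ 0 on [0,1]
        cfg = sim.SimConfig(thickness_mm=0.3, damping=30.0, growth_law=law)
        energies = []
        for _ in range(200):
            sim.step(state, cfg, mat)
            energies.append(state.elastic_energy + state.kinetic_energy)
        assert energies[-1] < 0.05 * energies[0]

    def test_momentum_stays_near_zero(self, tiny_ball_mesh):
        normed, _ = cf.normalize(tiny_ball_mesh)
        cfg = sim.SimConfig(thickness_mm=0.3)
        mat = sim.Material()
        state = sim.initialize(normed, cfg, mat, thickness_normalized=0.15)
        for _ in range(50):
            sim.step(state, cfg, mat)
        p = (state.masses[:, None] * state.vel).sum(axis=0)
        scale = (state.masses * np.linalg.norm(state.vel, axis=1)).sum()
        assert np.linalg.norm(p) < 1e-4 * max(scale, 1e-12)


class TestRun:
    def test_zero_end_time_returns_input_snapshot(self, tiny_ball_mesh):
        traj = sim.run(tiny_ball_mesh, sim.SimConfig(end_time=0.0))
        assert len(traj.snapshots) == 1
        np.testing.assert_allclose(
            traj.surface(0).vertices,
            traj.mesh.vertices[traj.surface_vertex_index])

    def test_subcritical_growth_stays_convex(self, tiny_ball_mesh):
        from corticofold import curvature as cv

        cfg = sim.SimConfig(thickness_mm=10.0, end_time=0.3,
                            snapshot_interval=0.1)
        traj = sim.run(tiny_ball_mesh, cfg)
        s = traj.surface(len(traj.snapshots) - 1)
        hull = cv.convex_hull_reference(traj.initial_surface(), s)
        assert cv.gyrification_index(s, hull) == pytest.approx(1.0, abs=0.02)

    def test_deterministic_given_same_inputs(self, tiny_ball_mesh):
        cfg = sim.SimConfig(thickness_mm=0.5, end_time=0.2)
        a = sim.run(tiny_ball_mesh, cfg)
        b = sim.run(tiny_ball_mesh, cfg)
        np.testing.assert_array_equal(a.snapshots[-1].boundary_coords,
                                      b.snapshots[-1].boundary_coords)

    def test_quasi_static_energy_ratio(self, tiny_ball_mesh):
        cfg = sim.SimConfig(thickness_mm=1.0, end_time=0.5,
                            snapshot_interval=0.1, damping=60.0)
        traj = sim.run(tiny_ball_mesh, cfg)
        for snap in traj.snapshots[2:]:
            if snap.elastic_energy > 1e-8:
                assert snap.kinetic_energy / snap.elastic_energy < 1e-2
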