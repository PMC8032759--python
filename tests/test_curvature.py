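import numpy as np
import pytest
import trimesh

from corticofold import curvature as cv


class TestVertexNormals:
    def test_sphere_normals_are_radial(self, unit_sphere_surface):
        vn = cv.vertex_normals(unit_sphere_surface)
        dots = np.einsum("ij,ij->i", vn, unit_sphere_surface.vertices)
        assert (dots > 0.999).all()

    def test_flipping_orientation_flips_normals(self, unit_sphere_surface):
        flipped = (unit_sphere_surface.vertices,
                   unit_sphere_surface.faces[:, ::-1])
        vn = cv.vertex_normals(unit_sphere_surface)
        vn_f = cv.vertex_normals(flipped)
        np.testing.assert_allclose(vn_f, -vn, atol=1e-12)


class TestCurvatureField:
    @pytest.mark.parametrize("radius", [1.0, 2.5])
    def test_sphere_principal_curvatures(self, radius):
        s = trimesh.creation.icosphere(subdivisions=4, radius=radius)
        f = cv.curvature_field(s)
        assert np.median(np.abs(f.k1 * radius - 1)) < 0.02
        assert np.median(np.abs(f.k2 * radius - 1)) < 0.02
        assert np.mean(np.abs(f.mean - 1 / radius)) / (1 / radius) < 0.02

    def test_cylinder_curvatures_and_directions(self, cylinder_surface):
        f = cv.curvature_field(cylinder_surface)
        # exclude open boundary rings (z extremes)
        z = np.asarray(cylinder_surface.vertices)[:, 2]
        inner = (z > 0.5) & (z < 3.5)
        assert np.median(np.abs(f.k1[inner] - 1.0)) < 0.03
        assert np.median(np.abs(f.k2[inner])) < 0.03
        # max-curvature direction is circumferential (perpendicular to z)
        assert np.median(np.abs(f.dir1[inner][:, 2])) < 0.05

    def test_sign_convention_convex_positive(self, unit_sphere_surface):
        f = cv.curvature_field(unit_sphere_surface)
        assert (f.mean > 0).all()

    def test_principal_directions_orthogonal(self, unit_sphere_surface):
        f = cv.curvature_field(unit_sphere_surface)
        dots = np.abs(np.einsum("ij,ij->i", f.dir1, f.dir2))
        assert dots.max() < 1e-6

    def test_eigendecomposition_consistent(self, cylinder_surface):
        f = cv.curvature_field(cylinder_surface)
        tr = f.II[:, 0, 0] + f.II[:, 1, 1]
        det = np.linalg.det(f.II)
        np.testing.assert_allclose(f.k1 + f.k2, tr, atol=1e-9)
        np.testing.assert_allclose(f.k1 * f.k2, det, atol=1e-9)
        assert (f.k1 >= f.k2 - 1e-12).all()


class TestDimensionlessCurvatureStat:
    def test_sphere_value_is_two_sqrt_pi(self, unit_sphere_surface):
        # (1/r) * sqrt(4 pi r^2) = 2 sqrt(pi), independent of radius
        stat = cv.dimensionless_curvature_stat(unit_sphere_surface)
        assert stat == pytest.approx(2 * np.sqrt(np.pi), rel=0.02)

    @pytest.mark.parametrize("scale", [0.1, 1.0, 10.0])
    def test_scale_invariance(self, unit_sphere_surface, scale):
        scaled = trimesh.Trimesh(
            vertices=np.asarray(unit_sphere_surface.vertices) * scale,
            faces=unit_sphere_surface.faces, process=False)
        a = cv.dimensionless_curvature_stat(unit_sphere_surface)
        b = cv.dimensionless_curvature_stat(scaled)
        assert b == pytest.approx(a, rel=1e-6)


class TestHullReference:
    def test_identity_when_deformed_equals_initial(self, unit_sphere_surface):
        hull = cv.convex_hull_reference(unit_sphere_surface, unit_sphere_surface)
        np.testing.assert_allclose(hull.vertices, unit_sphere_surface.vertices,
                                   atol=1e-12)

    def test_anisotropic_scaling_matches_bbox(self, unit_sphere_surface):
        deformed = trimesh.Trimesh(
            vertices=np.asarray(unit_sphere_surface.vertices) * [2.0, 1.0, 1.0],
            faces=unit_sphere_surface.faces, process=False)
        hull = cv.convex_hull_reference(unit_sphere_surface, deformed)
        ext = hull.vertices.max(axis=0) - hull.vertices.min(axis=0)
        np.testing.assert_allclose(ext, [4.0, 2.0, 2.0], rtol=1e-9)

    def test_spheroid_area_matches_closed_form(self, unit_sphere_surface):
        # prolate spheroid with semi-axes (2, 1, 1)
        deformed = trimesh.Trimesh(
            vertices=np.asarray(unit_sphere_surface.vertices) * [2.0, 1.0, 1.0],
            faces=unit_sphere_surface.faces, process=False)
        hull = cv.convex_hull_reference(unit_sphere_surface, deformed)
        a, c = 1.0, 2.0  # equatorial, polar
        e = np.sqrt(1 - a**2 / c**2)
        analytic = 2 * np.pi * a**2 * (1 + c / (a * e) * np.arcsin(e))
        assert cv.surface_area(hull) == pytest.approx(analytic, rel=0.01)

    def test_true_hull_mode(self, unit_sphere_surface):
        hull = cv.convex_hull_reference(None, unit_sphere_surface, mode="true")
        assert cv.surface_area(hull) == pytest.approx(
            cv.surface_area(unit_sphere_surface), rel=0.01)


class TestGyrificationIndex:
    def test_convex_surface_gi_is_one(self, unit_sphere_surface):
        hull = cv.convex_hull_reference(unit_sphere_surface, unit_sphere_surface)
        assert cv.gyrification_index(unit_sphere_surface, hull) == pytest.approx(
            1.0, abs=0.01)

    def test_gi_invariant_under_translation_scale_and_axis_swap(
            self, unit_sphere_surface):
        # the hull matching is axis-aligned, so the rigid motions that leave
        # GI exactly invariant are translations, global scalings and axis
        # permutations (the simulation geometries are axis-aligned)
        rng = np.random.default_rng(0)
        P = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        wob = np.asarray(unit_sphere_surface.vertices).copy()
        wob *= (1 + 0.1 * np.sin(5 * wob[:, 2]))[:, None]  # folded-ish surface
        deformed = trimesh.Trimesh(vertices=wob, faces=unit_sphere_surface.faces,
                                   process=False)
        hull = cv.convex_hull_reference(unit_sphere_surface, deformed)
        gi = cv.gyrification_index(deformed, hull)
        moved = trimesh.Trimesh(vertices=3.0 * wob @ P.T + rng.normal(size=3),
                                faces=unit_sphere_surface.faces, process=False)
        init_moved = trimesh.Trimesh(
            vertices=3.0 * np.asarray(unit_sphere_surface.vertices) @ P.T,
            faces=unit_sphere_surface.faces, process=False)
        hull2 = cv.convex_hull_reference(init_moved, moved)
        assert cv.gyrification_index(moved, hull2) == pytest.approx(gi, rel=1e-6)

    def test_definition_is_area_ratio(self, unit_sphere_surface):
        deformed = trimesh.Trimesh(
            vertices=np.asarray(unit_sphere_surface.vertices) * np.sqrt(2.8),
            faces=unit_sphere_surface.faces, process=False)
        assert cv.gyrification_index(deformed, unit_sphere_surface) == pytest.approx(
            2.8, rel=1e-9)


class TestSulcalDepth:
    def test_zero_depth_on_identity(self, unit_sphere_surface):
        d = cv.sulcal_depth(unit_sphere_surface, unit_sphere_surface,
                            unit_sphere_surface)
        assert np.nanmax(d.depth) < 1e-6

    def test_uniform_shrink_gives_constant_depth(self, unit_sphere_surface):
        shrunk = trimesh.Trimesh(
            vertices=np.asarray(unit_sphere_surface.vertices) * 0.8,
            faces=unit_sphere_surface.faces, process=False)
        d = cv.sulcal_depth(shrunk, unit_sphere_surface, unit_sphere_surface)
        np.testing.assert_allclose(d.depth, 0.2, atol=1e-9)

    def test_depth_nonnegative_and_misses_flagged(self, unit_sphere_surface):
        rng = np.random.default_rng(1)
        wob = np.asarray(unit_sphere_surface.vertices) * (
            1 - 0.2 * rng.random(len(unit_sphere_surface.vertices)))[:, None]
        deformed = trimesh.Trimesh(vertices=wob, faces=unit_sphere_surface.faces,
                                   process=False)
        d = cv.sulcal_depth(deformed, unit_sphere_surface, unit_sphere_surface)
        assert (d.depth >= -1e-12).all()

    def test_vertex_count_mismatch_rejected(self, unit_sphere_surface,
                                            cylinder_surface):
        with pytest.raises(ValueError):
            cv.sulcal_depth(cylinder_surface, unit_sphere_surface,
                            unit_sphere_surface)


class TestCurvatureCorrelation:
    def test_self_correlation_is_one(self, unit_sphere_surface):
        f = cv.curvature_field(unit_sphere_surface)
        assert cv.curvature_correlation(f, f) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(500)
        assert cv.curvature_correlation(a, -a) == pytest.approx(-1.0)

    def test_zero_variance_reported_missing(self):
        with pytest.warns(UserWarning):
            r = cv.curvature_correlation(np.ones(10), np.arange(10.0))
        assert np.isnan(r)
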