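"""Constrained quadric fitting and algebraic-to-geometric conversion."""

import numpy as np
import pytest

from lesionfit3d import (
    DegenerateGeometryError,
    InsufficientDataError,
    LesionEllipsoidModel,
    NotAnEllipsoidError,
    Quadric,
    ValidationError,
    fit_ellipsoid,
    fit_quadric,
    quadric_to_ellipsoid,
)

from conftest import (
    exact_ellipsoid_points,
    make_phantom,
    random_ellipsoid,
    random_rotation,
)


def oracle_unconstrained_fit(points):
    """Independent oracle: plain algebraic fit (SVD null vector, ||u||=1).

    For exact quadric-surface points the design matrix has a one-dimensional
    null space, so the smallest right singular vector is the quadric up to
    scale — no constraint machinery involved.  Geometric parameters are then
    extracted with an independent eigendecomposition.
    """
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    D = np.column_stack([x * x, y * y, z * z, 2 * y * z, 2 * x * z, 2 * x * y,
                         2 * x, 2 * y, 2 * z, np.ones_like(x)])
    u = np.linalg.svd(D)[2][-1]
    A = np.array([[u[0], u[5], u[4]], [u[5], u[1], u[3]], [u[4], u[3], u[2]]])
    b = u[6:9]
    center = np.linalg.solve(A, -b)
    d_c = u[9] + b @ center
    lam, _ = np.linalg.eigh(A)
    radii_sq = -d_c / lam
    assert np.all(radii_sq > 0), "oracle: not an ellipsoid"
    return center, np.sort(np.sqrt(radii_sq))[::-1]


class TestFitQuadric:
    def test_unit_sphere_coefficients(self):
        pts = exact_ellipsoid_points((0, 0, 0), (1, 1, 1), np.eye(3), n=40)
        q = fit_quadric(pts)
        coeffs = q.coefficients
        expected = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, -1], float)
        ratio = coeffs[0] / expected[0]
        assert np.allclose(coeffs, ratio * expected, atol=1e-9 * abs(ratio))

    def test_exact_recovery_of_rotated_translated_ellipsoid(self, rng):
        axes = np.array([20.0, 15.0, 10.0])
        R = random_rotation(rng)
        c = rng.uniform(-30, 30, 3)
        pts = exact_ellipsoid_points(c, axes, R, n=80)
        e = quadric_to_ellipsoid(fit_quadric(pts))
        assert np.abs(e.semi_axes - axes).max() < 1e-6
        assert np.abs(e.center - c).max() < 1e-6

    def test_coplanar_points_raise_rank_error(self, rng):
        pts = np.column_stack([rng.uniform(-5, 5, 12), rng.uniform(-5, 5, 12),
                               np.zeros(12)])
        with pytest.raises(DegenerateGeometryError):
            fit_quadric(pts)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_quadric(np.random.default_rng(0).normal(size=(9, 3)))

    def test_k_below_four_rejected(self, rng):
        pts = exact_ellipsoid_points((0, 0, 0), (5, 4, 3), np.eye(3), n=40)
        with pytest.raises(ValidationError):
            fit_quadric(pts, k=3.0)

    def test_constraint_satisfied_and_invariants_consistent(self, rng):
        # comparable semi-axes (ratio < 2): the k=4 constraint is active with
        # the positive sign; elongated shapes land on the |kJ - I^2| = 1 branch
        for _ in range(5):
            e = random_ellipsoid(rng, axis_range=(8.0, 14.0))
            q = fit_quadric(exact_ellipsoid_points(e.center, e.semi_axes,
                                                   e.rotation, n=60))
            assert q.k * q.J - q.I**2 == pytest.approx(1.0, abs=1e-8)
        for _ in range(5):
            e = random_ellipsoid(rng, axis_range=(5.0, 20.0))
            q = fit_quadric(exact_ellipsoid_points(e.center, e.semi_axes,
                                                   e.rotation, n=60))
            assert abs(q.k * q.J - q.I**2) == pytest.approx(1.0, abs=1e-8)

    def test_rigid_motion_equivariance(self, rng):
        """Rotating/translating the points moves centre/rotation accordingly
        and leaves semi-axes unchanged."""
        axes = np.array([18.0, 12.0, 7.0])
        base = exact_ellipsoid_points((0, 0, 0), axes, np.eye(3), n=80)
        for _ in range(20):
            R = random_rotation(rng)
            t = rng.uniform(-40, 40, 3)
            e = quadric_to_ellipsoid(fit_quadric(base @ R.T + t))
            assert np.abs(e.semi_axes - axes).max() < 1e-6
            assert np.abs(e.center - t).max() < 1e-6

    def test_scale_equivariance(self, rng):
        e0 = random_ellipsoid(rng)
        pts = exact_ellipsoid_points(e0.center, e0.semi_axes, e0.rotation, n=80)
        ref = quadric_to_ellipsoid(fit_quadric(pts))
        for s in (0.1, 3.7, 25.0):
            es = quadric_to_ellipsoid(fit_quadric(pts * s))
            assert np.allclose(es.semi_axes, ref.semi_axes * s, rtol=1e-9)

    def test_agrees_with_unconstrained_oracle(self, rng):
        for _ in range(5):
            e0 = random_ellipsoid(rng)
            pts = exact_ellipsoid_points(e0.center, e0.semi_axes, e0.rotation, n=80)
            c_o, axes_o = oracle_unconstrained_fit(pts)
            e = quadric_to_ellipsoid(fit_quadric(pts))
            assert np.abs(e.semi_axes - axes_o).max() < 1e-6
            assert np.abs(e.center - c_o).max() < 1e-6


class TestQuadricToEllipsoid:
    def test_unit_sphere(self):
        q = Quadric(1, 1, 1, 0, 0, 0, 0, 0, 0, -1)
        e = quadric_to_ellipsoid(q)
        assert np.allclose(e.center, 0)
        assert np.allclose(e.semi_axes, 1)

    def test_axis_aligned_closed_form(self):
        q = Quadric(1, 4, 9, 0, 0, 0, 0, 0, 0, -1)
        e = quadric_to_ellipsoid(q)
        assert np.allclose(e.semi_axes, [1.0, 0.5, 1.0 / 3.0])
        assert np.allclose(np.abs(e.rotation), np.eye(3), atol=1e-12)

    def test_hyperboloid_rejected(self):
        with pytest.raises(NotAnEllipsoidError):
            quadric_to_ellipsoid(Quadric(1, 1, -1, 0, 0, 0, 0, 0, 0, -1))

    def test_overall_sign_is_irrelevant(self):
        e1 = quadric_to_ellipsoid(Quadric(1, 4, 9, 0, 0, 0, 0, 0, 0, -1))
        e2 = quadric_to_ellipsoid(Quadric(-1, -4, -9, 0, 0, 0, 0, 0, 0, 1))
        assert np.allclose(e1.semi_axes, e2.semi_axes)

    def test_rotation_is_right_handed(self, rng):
        for _ in range(5):
            e0 = random_ellipsoid(rng)
            pts = exact_ellipsoid_points(e0.center, e0.semi_axes, e0.rotation, n=60)
            e = quadric_to_ellipsoid(fit_quadric(pts))
            assert np.linalg.det(e.rotation) == pytest.approx(1.0, abs=1e-9)


class TestFitEllipsoidMask:
    def test_sphere_on_isotropic_grid_within_5pct(self, sphere_phantom_iso):
        mask, truth = sphere_phantom_iso
        e = fit_ellipsoid(mask)
        assert np.all(np.abs(e.semi_axes - 10.0) / 10.0 < 0.05)

    def test_dwi_grid_ellipsoid_volume_within_15pct(self, dwi_paper_grid):
        mask, truth = make_phantom(dwi_paper_grid, (15.0, 10.0, 6.0),
                                   euler=(0, 30, 0), zoff=1.5)
        e = fit_ellipsoid(mask)
        tv = 4 * np.pi / 3 * np.prod(e.semi_axes) / 1000.0
        assert abs(tv - truth["tv_cc"]) / truth["tv_cc"] < 0.15

    def test_single_slice_mask_refused_by_default(self, dwi_paper_grid):
        # small flat lesion visible on one slice only (centre on a slice)
        mask, _ = make_phantom(dwi_paper_grid, (8.0, 8.0, 2.0), zoff=-3.0)
        assert len(mask.occupied_slices()) == 1
        with pytest.raises(InsufficientDataError):
            fit_ellipsoid(mask)
        e = fit_ellipsoid(mask, allow_single_slice=True)
        assert e.semi_axes[2] > 0

    def test_fit_is_deterministic(self, dwi_paper_grid):
        mask, _ = make_phantom(dwi_paper_grid, (12.0, 9.0, 7.0), euler=(20, 35, 0),
                               zoff=1.0)
        e1, e2 = fit_ellipsoid(mask), fit_ellipsoid(mask)
        assert np.array_equal(e1.semi_axes, e2.semi_axes)
        assert np.array_equal(e1.center, e2.center)
        assert np.array_equal(e1.rotation, e2.rotation)


class TestModelResultsAPI:
    def test_fit_returns_results_with_measurements(self, sphere_phantom_iso):
        mask, truth = sphere_phantom_iso
        res = LesionEllipsoidModel(mask).fit()
        assert res.tmd_cm == pytest.approx(truth["tmd_cm"], rel=0.05)
        assert res.tv_cc == pytest.approx(truth["tv_cc"], rel=0.10)
        assert res.n_points > 100
        text = res.summary()
        assert "semi-axes" in text and "TMD" in text and "TV" in text
        d = res.to_dict()
        assert set(d["quadric"]) == set("abcfghpqrd")

    def test_points_and_mask_are_mutually_exclusive(self, sphere_phantom_iso):
        mask, _ = sphere_phantom_iso
        with pytest.raises(ValidationError):
            LesionEllipsoidModel(mask=mask, points=np.zeros((10, 3)))
        with pytest.raises(ValidationError):
            LesionEllipsoidModel()

    def test_fit_from_points_matches_function_path(self, rng):
        e0 = random_ellipsoid(rng)
        pts = exact_ellipsoid_points(e0.center, e0.semi_axes, e0.rotation, n=60)
        res = LesionEllipsoidModel(points=pts).fit()
        assert np.abs(res.ellipsoid.semi_axes - e0.semi_axes).max() < 1e-6
        assert res.residual_rms < 1e-8
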