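import numpy as np
import pytest

from phenocloud import (Cylinder, CylinderRANSAC, cylinder_residual,
                        estimate_length, fit_ghm, fit_ransac)
from phenocloud.errors import DegenerateGeometryError

from conftest import cylinder_points, tilted_axis


def _axis_angle(a, b):
    return np.arccos(min(1.0, abs(np.dot(a, b))))


class TestResidual:
    def test_on_coat_point(self):
        cyl = Cylinder([0, 0, 0], [0, 0, 1], 2.0, h=0.0)
        assert cylinder_residual(cyl, [2, 0, 5]) == pytest.approx(0.0)

    def test_hand_value(self):
        cyl = Cylinder([0, 0, 0], [0, 0, 1], 2.0, h=0.0)
        assert cylinder_residual(cyl, [3, 0, 0]) == pytest.approx(1.0)

    def test_matches_axis_projection_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = tilted_axis(rng.uniform(0, 40), rng.uniform(0, 360))
            P = rng.uniform(-10, 10, 3)
            P[2] = 0.0
            r = rng.uniform(0.5, 4)
            q = rng.uniform(-20, 20, 3)
            # independent oracle: distance of q to the line (P, a), minus r
            w = q - P
            d_axis = np.linalg.norm(w - (w @ a) * a)
            got = cylinder_residual(Cylinder(P, a, r, h=0.0), q)
            assert got == pytest.approx(d_axis - r, abs=1e-12)


class TestGHM:
    def test_noise_free_exact_recovery(self):
        a = tilted_axis(10)
        pts = cylinder_points([5, 3, 0], a, 2.0, 100, 200)
        sol = fit_ghm(pts)
        assert sol.converged
        assert abs(sol.cylinder.radius - 2.0) < 1e-6
        assert _axis_angle(sol.cylinder.axis, a) < 1e-6
        assert np.abs(sol.residuals).max() < 1e-9

    def test_noisy_recovery_across_seeds(self):
        a = tilted_axis(10)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = cylinder_points([5, 3, 0], a, 2.0, 100, 200, sigma=0.05, rng=rng)
            sol = fit_ghm(pts)
            assert sol.converged
            assert abs(sol.cylinder.radius - 2.0) < 0.05
            assert np.degrees(_axis_angle(sol.cylinder.axis, a)) < 0.5

    def test_minimal_six_point_system_consistent(self):
        # well-spread six points exactly on a coat
        a = tilted_axis(8)
        ref = np.array([1.0, 0, 0])
        e1 = np.cross(a, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        heights = np.array([0, 20, 40, 60, 80, 100.0])
        phis = np.radians([0, 90, 180, 270, 45, 225.0])
        pts = (heights[:, None] * a
               + 2.0 * (np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2))
        sol = fit_ghm(pts)
        assert sol.converged
        assert np.abs(sol.residuals).max() < 1e-8

    def test_restrictions_satisfied(self):
        pts = cylinder_points([2, -4, 0], tilted_axis(20, 120), 1.5, 80, 150,
                              sigma=0.05)
        sol = fit_ghm(pts)
        assert abs(np.linalg.norm(sol.cylinder.axis) - 1.0) <= 1e-9
        assert abs(sol.cylinder.point[2] - sol.cylinder.h) <= 1e-9

    def test_residuals_reported_at_solution(self):
        pts = cylinder_points([0, 0, 0], tilted_axis(5), 2.0, 60, 100, sigma=0.05)
        sol = fit_ghm(pts)
        assert np.allclose(sol.residuals, cylinder_residual(sol.cylinder, pts),
                           atol=1e-9)

    def test_rigid_motion_equivariance(self):
        from scipy.spatial.transform import Rotation
        pts = cylinder_points([0, 0, 0], tilted_axis(12), 2.0, 90, 150, sigma=0.02)
        sol0 = fit_ghm(pts)
        R = Rotation.from_euler("xyz", [5, -8, 30], degrees=True).as_matrix()
        shift = np.array([10.0, -20.0, 5.0])
        sol1 = fit_ghm(pts @ R.T + shift)
        assert abs(sol0.cylinder.radius - sol1.cylinder.radius) < 1e-6
        assert _axis_angle(R @ sol0.cylinder.axis, sol1.cylinder.axis) < 1e-6

    def test_radius_estimate_unbiased(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(2000 + seed)
            pts = cylinder_points([0, 0, 0], tilted_axis(8), 1.5, 100, 200,
                                  sigma=0.05, rng=rng)
            errs.append(fit_ghm(pts).cylinder.radius - 1.5)
        assert abs(np.mean(errs)) < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ghm(np.zeros((5, 3)))

    def test_collinear_points_degenerate(self):
        pts = np.outer(np.arange(10.0), [0, 0, 1])
        with pytest.raises(DegenerateGeometryError):
            fit_ghm(pts)


class TestRANSAC:
    def test_clean_cluster_matches_full_fit(self):
        pts = cylinder_points([0, 0, 0], tilted_axis(10), 2.0, 100, 300, sigma=0.02)
        full = fit_ghm(pts)
        robust = fit_ransac(pts, seed=0)
        assert abs(full.cylinder.radius - robust.cylinder.radius) < 0.01

    def test_contaminated_cluster_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            a = tilted_axis(10)
            pts = cylinder_points([5, 3, 0], a, 2.0, 100, 200, sigma=0.05, rng=rng)
            out = rng.uniform(-25, 25, (70, 3)) + [5, 3, 50]
            d_axis = np.linalg.norm(np.cross(out - [5, 3, 0], a), axis=1)
            out = out[np.abs(d_axis - 2.0) > 5][:50]  # gross outliers only
            sol = fit_ransac(np.vstack([pts, out]), seed=seed)
            hits += abs(sol.cylinder.radius - 2.0) < 0.1
        assert hits >= 9

    def test_deterministic_under_seed(self):
        pts = cylinder_points([0, 0, 0], tilted_axis(15), 2.0, 80, 150, sigma=0.05)
        s1 = fit_ransac(pts, seed=11)
        s2 = fit_ransac(pts, seed=11)
        assert np.array_equal(s1.cylinder.point, s2.cylinder.point)
        assert s1.cylinder.radius == s2.cylinder.radius

    def test_estimator_interface(self):
        pts = cylinder_points([0, 0, 0], tilted_axis(10), 2.0, 100, 1500, sigma=0.05)
        est = CylinderRANSAC(seed=1).fit(pts)
        assert abs(est.radius_ - 2.0) < 0.05
        assert abs(est.length_ - 100) < 2.0
        assert est.predict(pts).shape == (1500,)
        assert CylinderRANSAC().get_params()["n_iter"] == 50


class TestLength:
    def test_full_span_recovered(self):
        pts = cylinder_points([0, 0, 0], [0, 0, 1], 2.0, 100, 2000)
        sol = fit_ghm(pts)
        cyl = estimate_length(sol.cylinder, pts)
        assert abs(cyl.length - 100) <= 1.0

    def test_single_slab_cluster(self):
        rng = np.random.default_rng(1)
        ph = rng.uniform(0, 2 * np.pi, 50)
        pts = np.column_stack([2 * np.cos(ph), 2 * np.sin(ph),
                               rng.uniform(0, 1.5, 50)])
        cyl = Cylinder([0, 0, 0.75], [0, 0, 1], 2.0, h=0.75)
        out = estimate_length(cyl, pts)
        assert out.length <= 2.0  # one slab quantum

    def test_occlusion_gap_stops_elongation(self):
        rng = np.random.default_rng(2)
        lower = cylinder_points([0, 0, 0], [0, 0, 1], 2.0, 45, 900, rng=rng)
        upper = cylinder_points([0, 0, 55], [0, 0, 1], 2.0, 45, 900, rng=rng)
        pts = np.vstack([lower, upper])
        cyl = Cylinder([0, 0, 50], [0, 0, 1], 2.0, h=50.0)
        out = estimate_length(cyl, pts, start_span=(-48.0, -47.0))
        # started at the bottom: growth must stop at the 10 mm gap
        assert out.length <= 46.0

    def test_no_coat_points_zero_length(self):
        pts = np.full((30, 3), 50.0)
        cyl = Cylinder([0, 0, 0], [0, 0, 1], 1.0, h=0.0)
        assert estimate_length(cyl, pts).length == 0.0

    def test_axis_flipped_upward(self):
        pts = cylinder_points([0, 0, 0], [0, 0, 1], 2.0, 50, 500)
        cyl = Cylinder([0, 0, 0], [0, 0, -1.0], 2.0, h=0.0)
        out = estimate_length(cyl, pts)
        assert out.axis[2] > 0
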