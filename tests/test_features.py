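import numpy as np
import pytest

from phenocloud import (FeatureParams, PointCloud, all_histograms,
                        estimate_normals, generate_plant, pair_features,
                        point_histogram, PlantSpec)
from phenocloud.errors import DegenerateGeometryError
from phenocloud.features import FeatureHistogramTransformer, histogram_matrix


def _darboux_reference(p_s, n_s, p_t, n_t):
    """Independent scalar evaluation of the Darboux-frame definition,
    including the source-selection rule."""
    t = np.asarray(p_t, float) - np.asarray(p_s, float)
    d = np.linalg.norm(t)
    t = t / d
    if abs(np.dot(n_s, t)) < abs(np.dot(n_t, t)):
        n_s, n_t, t = n_t, n_s, -t
    u = np.asarray(n_s, float)
    v = np.cross(u, t)
    if np.linalg.norm(v) < 1e-12:
        v = np.cross(u, [1.0, 0, 0])
        if np.linalg.norm(v) < 1e-12:
            v = np.cross(u, [0, 1.0, 0])
    v = v / np.linalg.norm(v)
    w = np.cross(u, v)
    return (np.dot(v, n_t), np.dot(u, t),
            np.arctan2(np.dot(w, n_t), np.dot(u, n_t)), d)


class TestNormals:
    def test_plane_gives_vertical_normals(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 30, (800, 2)), np.zeros(800)])
        cloud = estimate_normals(PointCloud(pts), 3.0, viewpoint=[0, 0, 100])
        inner = (pts[:, 0] > 3) & (pts[:, 0] < 27) & (pts[:, 1] > 3) & (pts[:, 1] < 27)
        assert np.abs(cloud.normals[inner] - [0, 0, 1]).max() < 1e-3

    def test_sphere_normals_radial(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(3000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = 10.0 * v
        cloud = estimate_normals(PointCloud(pts), 3.0, viewpoint=[0, 0, 1e5])
        dots = np.abs(np.einsum("ij,ij->i", cloud.normals, v))
        assert (dots > 0.99).all()

    def test_isolated_point_flagged_invalid(self):
        pts = np.vstack([np.random.default_rng(2).uniform(0, 5, (50, 3)),
                         [[100, 100, 100]]])
        cloud = estimate_normals(PointCloud(pts), 3.0)
        assert not cloud.valid_normals[-1]
        h = point_histogram(cloud, len(pts) - 1)
        assert not h.valid and h.values.sum() == 0


class TestPairFeatures:
    def test_parallel_normals_in_plane_translation(self):
        a, p, th, d = pair_features([0, 0, 0], [0, 0, 1], [1, 0, 0], [0, 0, 1])
        assert (a, p, th, d) == pytest.approx((0, 0, 0, 1))

    def test_swap_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ps, pt = rng.uniform(-5, 5, (2, 3))
            ns, nt = rng.normal(size=(2, 3))
            ns /= np.linalg.norm(ns)
            nt /= np.linalg.norm(nt)
            f1 = pair_features(ps, ns, pt, nt)
            f2 = pair_features(pt, nt, ps, ns)
            assert np.allclose(f1, f2, atol=1e-12)

    def test_matches_independent_frame_evaluation(self):
        cases = [
            ([0, 0, 0], [0, 0, 1], [1, 0, 0], [1, 0, 0]),
            ([0, 0, 0], [0, 0, 1], [1, 2, 0.5], [0, 1, 0]),
            ([1, -1, 2], [0.6, 0, 0.8], [2, 0, 1], [0, 0.8, -0.6]),
        ]
        for ps, ns, pt, nt in cases:
            got = pair_features(ps, ns, pt, nt)
            assert np.allclose(got, _darboux_reference(ps, ns, pt, nt), atol=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            pair_features([1, 1, 1], [0, 0, 1], [1, 1, 1], [0, 0, 1])


def _patch_plane(n=400, seed=0):
    rng = np.random.default_rng(seed)
    return np.column_stack([rng.uniform(0, 25, (n, 2)), np.zeros(n)])


def _patch_cylinder(r=2.0, n=400, seed=0):
    rng = np.random.default_rng(seed)
    ph = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, 40, n)
    return np.column_stack([r * np.cos(ph), r * np.sin(ph), z])


class TestHistograms:
    def test_shape_and_normalization(self):
        cloud = estimate_normals(PointCloud(_patch_plane()), 3.0)
        h = point_histogram(cloud, 10)
        assert len(h.values) == 125
        assert h.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert (h.values >= 0).all()

    def test_plane_vs_cylinder_patches_separate(self):
        plane = estimate_normals(PointCloud(_patch_plane()), 3.0)
        cyl = estimate_normals(PointCloud(_patch_cylinder()), 3.0)
        hp = np.mean([h.values for h in all_histograms(plane) if h.valid], axis=0)
        hc = np.mean([h.values for h in all_histograms(cyl) if h.valid], axis=0)
        assert np.abs(hp - hc).sum() > 0.2

    def test_collinear_cloud_all_invalid(self):
        cloud = estimate_normals(PointCloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]]), 3.0)
        assert all(not h.valid for h in all_histograms(cloud))

    def test_synthetic_plant_mostly_valid(self):
        cloud, _ = generate_plant(PlantSpec(n_stems=2, n_leaves=4, seed=5,
                                            stem_length=80, leaf_length=50))
        hists = all_histograms(estimate_normals(cloud, 3.0))
        assert np.mean([h.valid for h in hists]) >= 0.99

    def test_matches_pointwise_calls(self):
        cloud = estimate_normals(PointCloud(_patch_cylinder(n=120)), 3.0)
        hists = all_histograms(cloud)
        for i in (0, 17, 63):
            assert np.array_equal(hists[i].values, point_histogram(cloud, i).values)


class TestInvariances:
    def _hist_matrix(self, pts, viewpoint):
        cloud = estimate_normals(PointCloud(pts), 3.0, viewpoint=viewpoint)
        return histogram_matrix(all_histograms(cloud))[0]

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        pts = _patch_cylinder(n=250, seed=4)
        H0 = self._hist_matrix(pts, [0, 0, 1e4])
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        shift = np.array([12.0, -5.0, 30.0])
        H1 = self._hist_matrix(pts @ R.T + shift, R @ [0, 0, 1e4] + shift)
        assert np.abs(H0 - H1).sum(axis=1).max() < 1e-6

    def test_reordering_invariance(self):
        rng = np.random.default_rng(5)
        pts = _patch_cylinder(n=200, seed=5)
        perm = rng.permutation(len(pts))
        H0 = self._hist_matrix(pts, [0, 0, 1e4])
        H1 = self._hist_matrix(pts[perm], [0, 0, 1e4])
        # identical up to floating-point summation order: a pair feature
        # sitting within machine epsilon of a bin edge may hop one bin
        assert np.abs(H0[perm] - H1).sum(axis=1).max() < 0.04

    def test_uniform_scaling_with_radii(self):
        pts = _patch_cylinder(n=200, seed=6)
        c0 = estimate_normals(PointCloud(pts), 3.0, viewpoint=[0, 0, 1e4])
        c1 = estimate_normals(PointCloud(2 * pts), 6.0, viewpoint=[0, 0, 2e4])
        H0 = histogram_matrix(all_histograms(c0, FeatureParams(3, 15)))[0]
        H1 = histogram_matrix(all_histograms(c1, FeatureParams(6, 30)))[0]
        assert np.abs(H0 - H1).sum(axis=1).max() < 1e-9


class TestTransformer:
    def test_sklearn_shape_contract(self):
        pts = _patch_cylinder(n=150, seed=7)
        tf = FeatureHistogramTransformer()
        X = tf.fit(pts).transform(pts)
        assert X.shape == (150, 125)
        assert tf.get_params()["r_H"] == 15.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FeatureHistogramTransformer(r_N=20.0, r_H=15.0).fit(np.zeros((5, 3)))
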