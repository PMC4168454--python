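"""Surface feature histograms: per-point descriptors of local surface shape.

Each point of a (thinned, ~1 mm resolution) plant cloud gets a fixed-length
descriptor summarising the angular relations between its normal and the
normals/translations of every neighbour inside a radius ``r_H``. The three
pair features are the classical Darboux-frame angles: with source normal
``u = n_s``, ``v = u x t`` and ``w = u x v`` (``t`` the unit translation),

    alpha = v . n_t          (azimuthal relation of the two normals)
    phi   = u . t            (cosine of the polar angle of the translation)
    theta = atan2(w . n_t, u . n_t)

binned jointly with ``bins_per_feature`` equal-width bins per feature
(default 5, i.e. 125 bins). The translation length is computed for the
source-selection rule but not binned. Stems (thin cylinders) and leaves
(near-planar ribbons) produce clearly different histograms, which is what
the downstream SVM exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .cloud import PointCloud
from .errors import DegenerateGeometryError, EmptyCloudError


@dataclass(frozen=True)
class FeatureParams:
    """Histogram configuration.

    r_N : normal-estimation radius (mm); small enough to resolve the stem
        curvature, large enough to average sensor noise.
    r_H : histogram radius (mm); the neighbourhood each descriptor sees.
    bins_per_feature : equal-width bins per angular feature; the histogram
        has ``bins_per_feature ** 3`` entries.
    """

    r_N: float = 3.0
    r_H: float = 15.0
    bins_per_feature: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.r_N <= self.r_H:
            raise ValueError("require 0 < r_N <= r_H")
        if self.bins_per_feature < 2:
            raise ValueError("bins_per_feature must be >= 2")

    @property
    def n_bins(self) -> int:
        return self.bins_per_feature ** 3


@dataclass
class FeatureHistogram:
    """Normalized joint histogram describing one point's neighbourhood."""

    values: np.ndarray
    source_index: int
    valid: bool = True


def estimate_normals(cloud: PointCloud, r_N: float = 3.0,
                     viewpoint: np.ndarray | None = None) -> PointCloud:
    """Per-point unit normals by PCA over the ``r_N``-ball neighbourhood.

    The normal is the eigenvector of the local covariance with the smallest
    eigenvalue, sign-flipped to point toward ``viewpoint`` (default: far
    above the cloud, matching a scanner looking down on the plant). Points
    with fewer than 3 neighbours get a NaN normal and are flagged invalid.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("cannot estimate normals of an empty cloud")
    if r_N <= 0:
        raise ValueError("r_N must be positive")
    pts = cloud.points
    if viewpoint is None:
        viewpoint = pts.mean(axis=0) + np.array([0.0, 0.0, 1e4])
    viewpoint = np.asarray(viewpoint, dtype=np.float64)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r_N)
    normals = np.full((len(pts), 3), np.nan)
    covs = []
    rows = []
    for i, idx in enumerate(neighbors):
        if len(idx) < 4:  # point itself plus >= 3 neighbours
            continue
        local = pts[idx] - pts[idx].mean(axis=0)
        covs.append(local.T @ local / len(idx))
        rows.append(i)
    if rows:
        covs = np.stack(covs)
        # batched symmetric eigendecomposition; eigenvalues ascending
        _, vecs = np.linalg.eigh(covs)
        n = vecs[:, :, 0]
        rows = np.asarray(rows)
        flip = np.einsum("ij,ij->i", n, viewpoint - pts[rows]) < 0
        n[flip] *= -1.0
        normals[rows] = n / np.linalg.norm(n, axis=1, keepdims=True)
    return PointCloud(pts, cloud.labels, normals, _skip_validation=True)


def pair_features(p_s: np.ndarray, n_s: np.ndarray,
                  p_t: np.ndarray, n_t: np.ndarray,
                  reorder: bool = True) -> tuple[float, float, float, float]:
    """Darboux-frame pair features (alpha, phi, theta) and distance d.

    With ``reorder`` (default) the point whose normal makes the smaller
    angle with the translation becomes the source, which makes the triple
    symmetric under swapping the two points.
    """
    p_s = np.asarray(p_s, float)
    p_t = np.asarray(p_t, float)
    n_s = np.asarray(n_s, float)
    n_t = np.asarray(n_t, float)
    t = p_t - p_s
    d = float(np.linalg.norm(t))
    if d == 0.0:
        raise DegenerateGeometryError("coincident points have no pair features")
    t = t / d
    if reorder and abs(n_s @ t) < abs(n_t @ t):
        p_s, p_t, n_s, n_t, t = p_t, p_s, n_t, n_s, -t
    u = n_s
    v = np.cross(u, t)
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        # translation parallel to the source normal: the frame is defined
        # only up to rotation about u; pick any perpendicular
        v = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(v) < 1e-12:
            v = np.cross(u, [0.0, 1.0, 0.0])
        v = v / np.linalg.norm(v)
    else:
        v = v / nv
    w = np.cross(u, v)
    alpha = float(v @ n_t)
    phi = float(u @ t)
    theta = float(np.arctan2(w @ n_t, u @ n_t))
    return alpha, phi, theta, d


def _bin_indices(alpha: np.ndarray, phi: np.ndarray, theta: np.ndarray,
                 b: int) -> np.ndarray:
    ia = np.clip(((alpha + 1.0) / 2.0 * b).astype(int), 0, b - 1)
    ip = np.clip(((phi + 1.0) / 2.0 * b).astype(int), 0, b - 1)
    it = np.clip(((theta + np.pi) / (2.0 * np.pi) * b).astype(int), 0, b - 1)
    return (ia * b + ip) * b + it


def _pair_features_vec(p_s, n_s, P_t, N_t):
    """Vectorized pair features from one source against many targets."""
    t = P_t - p_s
    d = np.linalg.norm(t, axis=1)
    keep = d > 1e-12
    t = t[keep] / d[keep, None]
    N_t = N_t[keep]
    P_t = P_t[keep]
    m = len(t)
    if m == 0:
        return None
    # source-selection: the normal with the smaller angle to the translation
    S_n = np.broadcast_to(n_s, (m, 3)).copy()
    T_n = N_t.copy()
    swap = np.abs(t @ n_s) < np.abs((N_t * t).sum(1))
    if swap.any():
        S_n[swap] = N_t[swap]
        T_n[swap] = n_s
        t[swap] *= -1.0
    N_t = T_n
    u = S_n
    v = np.cross(u, t)
    nv = np.linalg.norm(v, axis=1)
    deg = nv < 1e-12
    if deg.any():
        alt = np.cross(u[deg], np.array([1.0, 0.0, 0.0]))
        bad = np.linalg.norm(alt, axis=1) < 1e-12
        if bad.any():
            alt[bad] = np.cross(u[deg][bad], np.array([0.0, 1.0, 0.0]))
        v[deg] = alt
        nv[deg] = np.linalg.norm(alt, axis=1)
    v = v / nv[:, None]
    w = np.cross(u, v)
    alpha = (v * N_t).sum(1)
    phi = (u * t).sum(1)
    theta = np.arctan2((w * N_t).sum(1), (u * N_t).sum(1))
    return alpha, phi, theta


def point_histogram(cloud: PointCloud, index: int,
                    params: FeatureParams = FeatureParams(),
                    _tree: cKDTree | None = None) -> FeatureHistogram:
    """Joint (alpha, phi, theta) histogram of one point vs. its ``r_H``-ball."""
    hists = _histograms_for(cloud, [index], params, _tree)
    return hists[0]


def all_histograms(cloud: PointCloud,
                   params: FeatureParams = FeatureParams()) -> list[FeatureHistogram]:
    """One histogram per point, in point order; invalid-normal points and
    points without a valid-normal neighbour are flagged invalid."""
    return _histograms_for(cloud, range(len(cloud)), params)


def _histograms_for(cloud, indices, params, tree=None):
    if cloud.normals is None:
        raise ValueError("cloud has no normals; call estimate_normals first")
    pts = cloud.points
    normals = cloud.normals
    valid = cloud.valid_normals
    if tree is None:
        tree = cKDTree(pts)
    b = params.bins_per_feature
    out = []
    zero = np.zeros(params.n_bins)
    for i in indices:
        if not valid[i]:
            out.append(FeatureHistogram(zero.copy(), i, valid=False))
            continue
        idx = np.asarray(tree.query_ball_point(pts[i], params.r_H))
        idx = idx[(idx != i) & valid[idx]]
        if len(idx) == 0:
            out.append(FeatureHistogram(zero.copy(), i, valid=False))
            continue
        feats = _pair_features_vec(pts[i], normals[i], pts[idx], normals[idx])
        if feats is None:
            out.append(FeatureHistogram(zero.copy(), i, valid=False))
            continue
        alpha, phi, theta = feats
        counts = np.bincount(_bin_indices(alpha, phi, theta, b),
                             minlength=params.n_bins).astype(float)
        out.append(FeatureHistogram(counts / counts.sum(), i, valid=True))
    return out


def histogram_matrix(histograms: list[FeatureHistogram]) -> tuple[np.ndarray, np.ndarray]:
    """Stack histograms to an (n, bins) matrix plus a validity mask."""
    X = np.stack([h.values for h in histograms])
    valid = np.array([h.valid for h in histograms], dtype=bool)
    return X, valid


class FeatureHistogramTransformer(BaseEstimator, TransformerMixin):
    """sklearn transformer: Nx3 coordinates -> (N, bins) histogram matrix.

    Stateless (``fit`` only validates); normals are estimated internally
    with radius ``r_N``. Rows for points whose histogram is invalid are
    all-zero; use :meth:`valid_mask` on the same input to recover them.
    """

    def __init__(self, r_N: float = 3.0, r_H: float = 15.0,
                 bins_per_feature: int = 5):
        self.r_N = r_N
        self.r_H = r_H
        self.bins_per_feature = bins_per_feature

    def _params(self) -> FeatureParams:
        return FeatureParams(self.r_N, self.r_H, self.bins_per_feature)

    def fit(self, X, y=None):
        self._params()  # validates
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        cloud = X if isinstance(X, PointCloud) else PointCloud(np.asarray(X, float))
        if cloud.normals is None:
            cloud = estimate_normals(cloud, self.r_N)
        hists = all_histograms(cloud, self._params())
        return histogram_matrix(hists)[0]

    def valid_mask(self, X) -> np.ndarray:
        cloud = X if isinstance(X, PointCloud) else PointCloud(np.asarray(X, float))
        if cloud.normals is None:
            cloud = estimate_normals(cloud, self.r_N)
        hists = all_histograms(cloud, self._params())
        return histogram_matrix(hists)[1]
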