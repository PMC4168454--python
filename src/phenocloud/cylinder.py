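"""Cylinder parameterization of stem clusters.

A stem cluster is modeled by the implicit cylinder condition

    Phi_i = || (P - Q_i) x a || - r = 0

for every coat point Q_i, with axis point P = (x_p, y_p, z_p), unit axis a
and radius r. The seven parameters are over-determined: the gauge freedoms
are removed by the two restrictions

    gamma_1 = ||a||  = 1        (unit axis)
    gamma_2 = z_p    = h        (P pinned to a freely selectable plane)

which turns the adjustment into a *restricted Gauss-Helmert model*: an
implicit least-squares condition in both the observations (the coat points,
which receive residual corrections v) and the parameters, plus equality
restrictions on the parameters alone. Each iteration linearizes

    A dx + B v + w1 = 0,     C dx = -w2

with A = dPhi/dx, B = dPhi/dQ, C = dgamma/dx, and solves the bordered
normal-equation system for the parameter update dx and the Lagrange
multipliers; v follows by back-substitution. Starting values are the
cluster centroid for P and the upright axis (0, 0, 1) — cereal stems grow
toward the top — with r the mean point-to-axis distance.

Robustness against misclassified leaf points comes from RANSAC over
six-point minimal subsets; the candidate with the smallest truncated
squared-residual sum is refined on its inliers. The cylinder length is then
found by elongating the fitted axis in slab steps while enough cluster
points stay within a coat tolerance (0.5 mm by default), and taking the
axial span of the accepted coat points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .cloud import PointCloud
from .errors import DegenerateGeometryError, FitError


@dataclass
class Cylinder:
    """Axis point P (with z_p pinned to the plane height h), unit axis a,
    radius r, and (after length estimation) the coat length in mm."""

    point: np.ndarray
    axis: np.ndarray
    radius: float
    h: float
    length: float | None = None

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, float).reshape(3)
        self.axis = np.asarray(self.axis, float).reshape(3)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("cylinder axis must be a unit vector")
        if abs(self.point[2] - self.h) > 1e-9:
            raise ValueError("axis point must lie in the plane z = h")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def cylinder_residual(cyl: Cylinder, q: np.ndarray) -> float | np.ndarray:
    """Signed distance of point(s) q to the cylinder coat:
    ``||(P - q) x a|| - r`` (zero iff q lies on the coat)."""
    q = np.asarray(q, float)
    single = q.ndim == 1
    b = cyl.point - np.atleast_2d(q)
    return_val = np.linalg.norm(np.cross(b, cyl.axis), axis=1) - cyl.radius
    return float(return_val[0]) if single else return_val


@dataclass
class GHMSolution:
    cylinder: Cylinder
    residuals: np.ndarray
    iterations: int
    converged: bool
    inlier_mask: np.ndarray | None = field(default=None)

    @property
    def rms_residual(self) -> float:
        return float(np.sqrt(np.mean(self.residuals ** 2)))


def _gauge_fix(P: np.ndarray, a: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Exactly re-impose ||a|| = 1 and z_p = h (pure re-parameterization)."""
    a = a / np.linalg.norm(a)
    if a[2] < 0:
        a = -a
    if abs(a[2]) > 0.1:
        P = P + ((h - P[2]) / a[2]) * a
    else:
        P = np.array([P[0], P[1], h])
    return P, a


def fit_ghm(points: np.ndarray, x0: Cylinder | None = None, h: float | None = None,
            tol: float = 1e-8, max_iter: int = 100) -> GHMSolution:
    """Restricted Gauss-Helmert least-squares cylinder fit.

    Parameters
    ----------
    points : (n >= 6, 3) array of coat observations (mm).
    x0 : optional starting cylinder; default is the centroid / upright-axis
        initialization described in the module docstring.
    h : height of the plane pinning z_p; default is the centroid z (keeps
        the axis point inside the data).
    """
    Q = np.asarray(points, float).reshape(-1, 3)
    n = len(Q)
    if n < 6:
        raise ValueError("a cylinder fit needs at least 6 points")
    centroid = Q.mean(axis=0)
    if h is None:
        h = float(x0.h) if x0 is not None else float(centroid[2])
    if x0 is None:
        P = np.array([centroid[0], centroid[1], h])
        a = np.array([0.0, 0.0, 1.0])
        r = float(np.mean(np.linalg.norm(np.cross(P - Q, a), axis=1)))
        if r < 1e-9:
            raise DegenerateGeometryError("points are collinear with the start axis")
    else:
        P, a, r = x0.point.copy(), x0.axis.copy(), float(x0.radius)
    v = np.zeros_like(Q)  # residual corrections to the observations
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Qh = Q + v
        b = P - Qh
        u = np.cross(b, a)
        s = np.linalg.norm(u, axis=1)
        if np.any(s < 1e-12):
            raise DegenerateGeometryError("a point lies on the cylinder axis")
        uh = u / s[:, None]
        a_x_uh = np.cross(np.broadcast_to(a, uh.shape), uh)
        b_x_uh = np.cross(b, uh)
        # A = dPhi/dx rows [dP | da | dr], B = dPhi/dQ
        A = np.hstack([a_x_uh, -b_x_uh, -np.ones((n, 1))])
        B = -a_x_uh  # (n, 3) row blocks of the block-diagonal B
        phi = s - r
        w1 = phi - np.einsum("ij,ij->i", B, v)
        W = 1.0 / np.einsum("ij,ij->i", B, B)
        na = np.linalg.norm(a)
        C = np.zeros((2, 7))
        C[0, 3:6] = a / na
        C[1, 2] = 1.0
        w2 = np.array([na - 1.0, P[2] - h])
        N = A.T @ (W[:, None] * A)
        K = np.zeros((9, 9))
        K[:7, :7] = N
        K[:7, 7:] = C.T
        K[7:, :7] = C
        rhs = np.concatenate([-A.T @ (W * w1), -w2])
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular normal matrix: {exc}") from exc
        dx = sol[:7]
        # damp steps that would drive the radius non-positive (minimal
        # six-point systems can overshoot badly in the first iterations)
        scale = 1.0
        while r + scale * dx[6] <= 1e-9 and scale > 1e-8:
            scale *= 0.5
        if scale <= 1e-8:
            break  # stalled; reported as non-converged
        dx = dx * scale
        v = -(W * (A @ dx + w1))[:, None] * B
        P = P + dx[:3]
        a = a + dx[3:6]
        r = float(r + dx[6])
        if np.linalg.norm(dx) < tol:
            converged = True
            break
    P, a = _gauge_fix(P, a, h)
    cyl = Cylinder(P, a, r, h)
    return GHMSolution(cyl, cylinder_residual(cyl, Q), it, converged)


def fit_ransac(points: PointCloud | np.ndarray, n_iter: int = 50,
               sample_size: int = 6, seed: int = 0,
               inlier_tol: float = 1.0) -> GHMSolution:
    """Robust cylinder fit by repeated minimal six-point adjustments.

    Each candidate is scored by the truncated squared-residual sum over all
    cluster points (residuals saturate at ``inlier_tol``, so out-of-band
    points contribute a constant penalty); the smallest-discrepancy
    candidate is refined on its inliers.
    """
    Q = points.points if isinstance(points, PointCloud) else np.asarray(points, float)
    n = len(Q)
    if n < sample_size:
        raise ValueError(f"cluster has {n} < {sample_size} points")
    rng = np.random.default_rng(seed)
    h = float(Q.mean(axis=0)[2])
    best_score = np.inf
    best: GHMSolution | None = None
    for _ in range(n_iter):
        sel = rng.choice(n, sample_size, replace=False)
        try:
            cand = fit_ghm(Q[sel], h=h, max_iter=50)
        except (FitError, DegenerateGeometryError):
            continue
        if not cand.converged:
            continue
        res = cylinder_residual(cand.cylinder, Q)
        score = float(np.sum(np.minimum(res ** 2, inlier_tol ** 2)))
        if score < best_score:
            best_score = score
            best = GHMSolution(cand.cylinder, res, cand.iterations, True,
                               np.abs(res) < inlier_tol)
    if best is None:
        raise FitError("no RANSAC candidate converged")
    inliers = best.inlier_mask
    if inliers.sum() >= 6:
        try:
            refined = fit_ghm(Q[inliers], x0=best.cylinder, h=h)
            if refined.converged:
                res = cylinder_residual(refined.cylinder, Q)
                best = GHMSolution(refined.cylinder, res, refined.iterations,
                                   True, np.abs(res) < inlier_tol)
        except (FitError, DegenerateGeometryError):
            pass
    return best


def estimate_length(cyl: Cylinder, cluster: PointCloud | np.ndarray,
                    coat_tol: float = 0.5, slab: float = 2.0,
                    min_pts: int = 2,
                    start_span: tuple[float, float] | None = None) -> Cylinder:
    """Length by axis elongation.

    Cluster points within ``coat_tol`` of the coat are projected on the
    axis; starting from ``start_span`` (default: one slab around the median
    coat point) the accepted interval grows by ``slab``-height steps in both
    directions while each new slab holds at least ``min_pts`` coat points.
    The length is the axial span of the accepted coat points; if no point is
    within tolerance the cylinder is flagged with zero length.
    """
    Q = cluster.points if isinstance(cluster, PointCloud) else np.asarray(cluster, float)
    res = cylinder_residual(cyl, Q)
    coat = np.abs(res) <= coat_tol
    axis = cyl.axis if cyl.axis[2] >= 0 else -cyl.axis
    if not coat.any():
        return Cylinder(cyl.point, axis, cyl.radius, cyl.h, length=0.0)
    t = (Q[coat] - cyl.point) @ axis
    if start_span is None:
        m = float(np.median(t))
        lo, hi = m - slab / 2, m + slab / 2
    else:
        lo, hi = float(start_span[0]), float(start_span[1])
    while np.count_nonzero((t > hi) & (t <= hi + slab)) >= min_pts:
        hi += slab
    while np.count_nonzero((t < lo) & (t >= lo - slab)) >= min_pts:
        lo -= slab
    accepted = t[(t >= lo - slab) & (t <= hi + slab)]
    length = float(accepted.max() - accepted.min()) if len(accepted) else 0.0
    return Cylinder(cyl.point, axis, cyl.radius, cyl.h, length=length)


class CylinderRANSAC(BaseEstimator):
    """sklearn-style estimator wrapping the robust fit + length estimation.

    ``fit(X)`` takes an (n, 3) array of cluster coordinates and exposes
    ``axis_point_``, ``axis_``, ``radius_``, ``length_``, ``residuals_``,
    ``inlier_mask_`` and ``converged_``.
    """

    def __init__(self, n_iter: int = 50, sample_size: int = 6,
                 inlier_tol: float = 1.0, coat_tol: float = 0.5,
                 slab: float = 2.0, min_pts: int = 2, seed: int = 0):
        self.n_iter = n_iter
        self.sample_size = sample_size
        self.inlier_tol = inlier_tol
        self.coat_tol = coat_tol
        self.slab = slab
        self.min_pts = min_pts
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        sol = fit_ransac(X, self.n_iter, self.sample_size, self.seed,
                         self.inlier_tol)
        cyl = estimate_length(sol.cylinder, X, self.coat_tol, self.slab,
                              self.min_pts)
        self.cylinder_ = cyl
        self.axis_point_ = cyl.point
        self.axis_ = cyl.axis
        self.radius_ = cyl.radius
        self.length_ = cyl.length
        self.residuals_ = sol.residuals
        self.inlier_mask_ = sol.inlier_mask
        self.converged_ = sol.converged
        return self

    def predict(self, X):
        """Signed coat distance of new points (mm)."""
        return cylinder_residual(self.cylinder_, np.asarray(X, float))
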