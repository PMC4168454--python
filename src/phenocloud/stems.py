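"""Stem counting by spherical direction voting and per-stem clustering.

Tillers are nearly straight, so a line fit through a handful of stem points
recovers a stem's axis direction with high probability. The cloud (centered
at its center of gravity) is split into the eight Euclidean octants; in each
octant many five-point line fits are drawn and their principal directions
are binned on the unit sphere by azimuth phi in [0, 360) and polar angle
omega in [0, 180] (10 degree steps by default). Each tiller produces one
dominant connected region of high votes; thresholding the accumulator and
counting connected regions yields the stem count, which then fixes the cut
level of a single-linkage clustering that separates the individual stems.

Directions are sign-ambiguous (+/-a describe the same line) and are
canonicalized to the upper hemisphere before binning — stems grow upward,
and without this each stem would vote at two antipodal maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import Delaunay, QhullError

from .cloud import PointCloud, center_of_gravity
from .errors import DegenerateGeometryError, EmptyCloudError


@dataclass
class DirectionAccumulator:
    """Vote grid over (omega, phi): rows are polar bins, columns azimuth bins."""

    counts: np.ndarray  # (180/step, 360/step) int array
    step_deg: float

    @property
    def total_votes(self) -> int:
        return int(self.counts.sum())

    def bin_center_direction(self, i_omega: int, i_phi: int) -> np.ndarray:
        om = np.radians((i_omega + 0.5) * self.step_deg)
        ph = np.radians((i_phi + 0.5) * self.step_deg)
        return np.array([np.sin(om) * np.cos(ph), np.sin(om) * np.sin(ph),
                         np.cos(om)])

    def to_csv(self, path) -> None:
        """Heat-map export: one row per omega bin, one column per phi bin."""
        np.savetxt(path, self.counts, fmt="%d", delimiter=",")


@dataclass
class StemClusterSet:
    k: int
    assignment: np.ndarray  # per-point cluster index in [0, k)


def canonical_direction(v: np.ndarray) -> np.ndarray:
    """Unit direction mapped to the z >= 0 hemisphere (ties: x, then y >= 0)."""
    v = np.asarray(v, float)
    v = v / np.linalg.norm(v)
    if v[2] < 0 or (v[2] == 0 and (v[0] < 0 or (v[0] == 0 and v[1] < 0))):
        v = -v
    return v


def line_fit_direction(points: np.ndarray) -> np.ndarray:
    """Principal direction of a small point set, canonicalized to z >= 0."""
    pts = np.asarray(points, float)
    c = pts - pts.mean(axis=0)
    if not np.any(np.abs(c) > 1e-12):
        raise DegenerateGeometryError("all points coincide; no line direction")
    _, vecs = np.linalg.eigh(c.T @ c)
    return canonical_direction(vecs[:, -1])


def vote_directions(cloud: PointCloud, fits_per_octant: int = 1000,
                    step_deg: float = 10.0, seed: int = 0) -> DirectionAccumulator:
    """Octant-wise repeated five-point line fits binned on the sphere.

    Deterministic for a fixed seed; invariant to point order up to the
    random sampling (points are addressed per octant, not by index order).
    """
    if len(cloud) == 0:
        raise EmptyCloudError("cannot vote on an empty cloud")
    pts = cloud.points - center_of_gravity(cloud)
    octant = ((pts[:, 0] >= 0).astype(int) * 4
              + (pts[:, 1] >= 0).astype(int) * 2
              + (pts[:, 2] >= 0).astype(int))
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))  # point-order invariance
    rng = np.random.default_rng(seed)
    n_om = int(round(180.0 / step_deg))
    n_ph = int(round(360.0 / step_deg))
    counts = np.zeros((n_om, n_ph), dtype=np.int64)
    any_octant = False
    for o in range(8):
        idx = order[octant[order] == o]
        if len(idx) < 5:
            continue
        any_octant = True
        sel = np.empty((fits_per_octant, 5), dtype=np.int64)
        for f in range(fits_per_octant):
            sel[f] = rng.choice(len(idx), 5, replace=False)
        samples = pts[idx[sel]]                      # (fits, 5, 3)
        centered = samples - samples.mean(axis=1, keepdims=True)
        cov = np.einsum("fij,fik->fjk", centered, centered)
        ok = np.abs(centered).max(axis=(1, 2)) > 1e-12
        if not ok.any():
            continue
        _, vecs = np.linalg.eigh(cov[ok])
        d = vecs[:, :, -1]
        flip = (d[:, 2] < 0) | ((d[:, 2] == 0) & (d[:, 0] < 0))
        d[flip] *= -1.0
        om = np.degrees(np.arccos(np.clip(d[:, 2], -1.0, 1.0)))
        ph = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0
        i_om = np.clip((om / step_deg).astype(int), 0, n_om - 1)
        i_ph = np.clip((ph / step_deg).astype(int), 0, n_ph - 1)
        np.add.at(counts, (i_om, i_ph), 1)
    if not any_octant:
        raise DegenerateGeometryError("no octant holds the 5 points a line fit needs")
    return DirectionAccumulator(counts, step_deg)


def count_stems(acc: DirectionAccumulator, threshold_frac: float = 0.20
                ) -> tuple[int, list[np.ndarray]]:
    """Threshold the accumulator and count connected vote regions.

    Bins reaching ``threshold_frac`` of the maximum bin count are set; the
    set bins are grouped 8-connected with azimuth wraparound, and all set
    bins of the polar cap row (omega < one step) are merged — they represent
    nearly identical near-vertical directions. Returns the region count and
    each region's vote-weighted mean direction.
    """
    if acc.total_votes < 1:
        raise ValueError("accumulator holds no votes")
    binary = acc.counts >= threshold_frac * acc.counts.max()
    lab, n_lab = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    parent = list(range(n_lab + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # azimuth wraparound: first and last column are neighbours (incl. diagonal)
    n_om = lab.shape[0]
    for i in range(n_om):
        for di in (-1, 0, 1):
            j = i + di
            if 0 <= j < n_om and lab[i, 0] and lab[j, -1]:
                union(lab[i, 0], lab[j, -1])
    # polar cap: all set bins of row 0 are essentially the same direction
    cap = [l for l in np.unique(lab[0]) if l != 0]
    for l in cap[1:]:
        union(cap[0], l)
    roots = sorted({find(l) for l in range(1, n_lab + 1)})
    k = len(roots)
    directions = []
    for r in roots:
        members = [l for l in range(1, n_lab + 1) if find(l) == r]
        mask = np.isin(lab, members)
        w = acc.counts * mask
        vec = np.zeros(3)
        for i_om, i_ph in zip(*np.nonzero(mask)):
            vec += w[i_om, i_ph] * acc.bin_center_direction(i_om, i_ph)
        directions.append(canonical_direction(vec))
    return k, directions


def cluster_stems(stem_points: PointCloud, k: int,
                  method: str = "auto") -> StemClusterSet:
    """Cut a single-linkage (Euclidean) hierarchy at ``k`` clusters.

    ``method="hierarchy"`` uses the scipy agglomerative hierarchy directly;
    ``method="mst"`` uses the equivalent formulation — remove the k-1
    largest edges of the Euclidean minimum spanning tree — computed from the
    Delaunay edge set (which contains the EMST). ``"auto"`` picks the
    hierarchy for small clouds and the MST route for large ones, where the
    dense distance matrix would be wasteful.
    """
    n = len(stem_points)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot split {n} points into {k} clusters")
    if k == 1:
        return StemClusterSet(1, np.zeros(n, dtype=np.int64))
    pts = stem_points.points
    if method == "hierarchy" or (method == "auto" and n <= 3000):
        z = linkage(pts, method="single")
        assign = fcluster(z, t=k, criterion="maxclust") - 1
        return StemClusterSet(int(assign.max()) + 1, assign.astype(np.int64))
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    simp = tri.simplices
    edges = set()
    for a in range(simp.shape[1]):
        for b in range(a + 1, simp.shape[1]):
            edges.update(map(tuple, np.sort(simp[:, [a, b]], axis=1)))
    e = np.array(sorted(edges))
    w = np.linalg.norm(pts[e[:, 0]] - pts[e[:, 1]], axis=1)
    g = coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
    mst = minimum_spanning_tree(g).tocoo()
    order = np.argsort(mst.data)[::-1]
    keep = np.ones(len(mst.data), dtype=bool)
    keep[order[: k - 1]] = False
    g2 = coo_matrix((mst.data[keep], (mst.row[keep], mst.col[keep])), shape=(n, n))
    n_comp, assign = connected_components(g2, directed=False)
    return StemClusterSet(int(n_comp), assign.astype(np.int64))
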