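"""Leaf segmentation, surface meshing and area computation.

Leaves of a thinned plant scan are near-developable ribbons sampled at
~1 mm. Each leaf-labeled connected component is meshed by isometric
unrolling: the point set is flattened to the plane with Isomap (geodesic
distances over the neighbour graph), which for a developable surface is an
isometry up to sampling error, then triangulated by a single global 2D
Delaunay triangulation of the flattened coordinates. Triangles whose 3D
edge length exceeds ``max_edge`` (default 3 mm, three times the sampling
pitch) are discarded, which trims the convex-hull fill outside the true
boundary. Occlusion holes are left open — the contract is area accuracy,
not watertightness. Leaf area is the summed triangle area over the original
3D vertices, cumulated leaf area the sum over leaves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, cKDTree
from sklearn.manifold import Isomap

from .cloud import PointCloud
from .errors import DegenerateGeometryError


@dataclass
class LeafMesh:
    """Triangle mesh of one leaf: vertices (mm), index triples, area (mm^2)."""

    vertices: np.ndarray
    triangles: np.ndarray
    area: float

    def export_ply(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(self.vertices)}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {len(self.triangles)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for t in self.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    v0 = vertices[triangles[:, 0]]
    e1 = vertices[triangles[:, 1]] - v0
    e2 = vertices[triangles[:, 2]] - v0
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def segment_leaves(leaf_points: PointCloud, connect_radius: float = 3.0,
                   min_points: int = 20) -> list[np.ndarray]:
    """Connected components of the radius graph over leaf-labeled points.

    Returns index arrays into ``leaf_points``; fragments smaller than
    ``min_points`` are discarded.
    """
    n = len(leaf_points)
    if n == 0:
        return []
    tree = cKDTree(leaf_points.points)
    pairs = tree.query_pairs(connect_radius, output_type="ndarray")
    graph = csr_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                       shape=(n, n))
    _, comp = connected_components(graph, directed=False)
    out = []
    for c in range(comp.max() + 1):
        idx = np.flatnonzero(comp == c)
        if len(idx) >= min_points:
            out.append(idx)
    return out


def _flatten(pts: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Isomap embedding to the plane; grows the neighbourhood if the
    neighbour graph is disconnected."""
    last_exc: Exception | None = None
    for k in (n_neighbors, 2 * n_neighbors, 4 * n_neighbors):
        if k >= len(pts):
            break
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return Isomap(n_neighbors=k, n_components=2).fit_transform(pts)
        except Exception as exc:  # disconnected graph, eigensolver failure
            last_exc = exc
    raise DegenerateGeometryError(f"cannot flatten leaf point set: {last_exc}")


def mesh_leaf(points: PointCloud | np.ndarray, max_edge: float = 3.0,
              n_neighbors: int = 10) -> LeafMesh:
    """Triangulate one leaf's point set by isometric unrolling.

    Raises :class:`DegenerateGeometryError` for degenerate (e.g. collinear)
    input where no 2D triangulation exists.
    """
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, float)
    if len(pts) < 4:
        raise DegenerateGeometryError("too few points to mesh")
    emb = _flatten(pts, n_neighbors)
    try:
        tris = Delaunay(emb).simplices
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"degenerate (collinear?) leaf point set: {exc}") from exc
    e = np.stack([
        np.linalg.norm(pts[tris[:, 0]] - pts[tris[:, 1]], axis=1),
        np.linalg.norm(pts[tris[:, 1]] - pts[tris[:, 2]], axis=1),
        np.linalg.norm(pts[tris[:, 0]] - pts[tris[:, 2]], axis=1),
    ])
    tris = tris[e.max(axis=0) <= max_edge]
    areas = triangle_areas(pts, tris)
    tris = tris[areas > 1e-12]
    if len(tris) == 0:
        raise DegenerateGeometryError("no triangles within the edge-length cap")
    used = np.unique(tris)
    remap = np.full(len(pts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = LeafMesh(pts[used], remap[tris], 0.0)
    mesh.area = float(triangle_areas(mesh.vertices, mesh.triangles).sum())
    return mesh


def cumulated_leaf_area(meshes: list[LeafMesh]) -> float:
    """Sum of member areas (mm^2); 0 for an empty list."""
    return float(sum(m.area for m in meshes))
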