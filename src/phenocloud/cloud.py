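"""Point-cloud data model, file I/O and resolution thinning.

Clouds are unordered 3D point sets in millimetres, optionally carrying a
per-point organ label (leaf / stem / unknown) and a per-point unit normal.
Normals that could not be estimated (too few neighbours) are stored as NaN
rows and flagged invalid rather than dropped, so point indexing stays stable
across the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CloudParseError, EmptyCloudError

# organ label codes (uchar in PLY files)
LEAF = 0
STEM = 1
UNKNOWN = 2

LABEL_NAMES = {LEAF: "leaf", STEM: "stem", UNKNOWN: "unknown"}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class PointCloud:
    """Unordered 3D points in mm with optional labels and normals.

    Parameters
    ----------
    points : (n, 3) float array
        Cartesian coordinates in millimetres.
    labels : (n,) int array, optional
        Per-point organ code (``LEAF``, ``STEM`` or ``UNKNOWN``).
    normals : (n, 3) float array, optional
        Per-point unit normals; rows of NaN mark points whose normal could
        not be estimated.
    """

    points: np.ndarray
    labels: np.ndarray | None = None
    normals: np.ndarray | None = None
    _skip_validation: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
        if self._skip_validation:
            return
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ValueError("labels must have the same length as points")
        if self.normals is not None:
            if len(self.normals) != len(self.points):
                raise ValueError("normals must have the same length as points")
            norms = np.linalg.norm(self.normals, axis=1)
            ok = np.isnan(norms) | (np.abs(norms - 1.0) <= 1e-6)
            if not ok.all():
                raise ValueError("normals must be unit vectors (or NaN if invalid)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    @property
    def valid_normals(self) -> np.ndarray:
        """Boolean mask of points carrying a finite (estimated) normal."""
        if self.normals is None:
            return np.zeros(len(self), dtype=bool)
        return np.isfinite(self.normals).all(axis=1)

    def select(self, mask_or_index: np.ndarray) -> "PointCloud":
        """Sub-cloud at the given boolean mask / index array."""
        return PointCloud(
            self.points[mask_or_index],
            None if self.labels is None else self.labels[mask_or_index],
            None if self.normals is None else self.normals[mask_or_index],
            _skip_validation=True,
        )

    def with_labels(self, labels: np.ndarray) -> "PointCloud":
        return PointCloud(self.points, labels, self.normals, _skip_validation=True)


def center_of_gravity(cloud: PointCloud) -> np.ndarray:
    """Arithmetic mean of the coordinates (mm)."""
    if len(cloud) == 0:
        raise EmptyCloudError("cannot take the center of gravity of an empty cloud")
    return cloud.points.mean(axis=0)


def thin_to_resolution(cloud: PointCloud, min_spacing: float) -> PointCloud:
    """Subsample to a homogeneous resolution.

    Greedy pass in input order over a voxel hash: a point is kept iff no
    previously kept point lies within ``min_spacing``. Kept points retain
    their labels/normals; every pair of output points is >= ``min_spacing``
    apart and the output is a subset of the input.
    """
    if min_spacing <= 0:
        raise ValueError("min_spacing must be positive")
    if len(cloud) == 0:
        raise EmptyCloudError("cannot thin an empty cloud")
    kept = thin_indices(cloud.points, min_spacing)
    return cloud.select(kept)


def thin_indices(points: np.ndarray, min_spacing: float) -> np.ndarray:
    """Indices kept by the greedy thinning pass (see :func:`thin_to_resolution`)."""
    pts = np.asarray(points, dtype=np.float64)
    s = float(min_spacing)
    voxels = np.floor(pts / s).astype(np.int64)
    grid: dict[tuple[int, int, int], list[int]] = {}
    kept: list[int] = []
    s2 = s * s
    for i in range(len(pts)):
        vx, vy, vz = voxels[i]
        p = pts[i]
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((vx + dx, vy + dy, vz + dz), ()):
                        d = pts[j] - p
                        if d @ d < s2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((vx, vy, vz), []).append(i)
            kept.append(i)
    return np.asarray(kept, dtype=np.int64)


# ---------------------------------------------------------------------------
# File I/O: XYZ text and PLY (ascii / binary_little_endian)
# ---------------------------------------------------------------------------

def read_cloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Read a point cloud from an XYZ text file or a PLY file.

    The format is inferred from the suffix when not given. XYZ lines are
    ``x y z [label]`` with ``#`` comments; the label column accepts either
    the names leaf/stem/unknown or the integer codes 0/1/2.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "ply":
        return _read_ply(path)
    raise ValueError(f"unknown cloud format: {fmt!r}")


def write_cloud(cloud: PointCloud, path: str | Path, format: str | None = None,
                binary: bool = False) -> None:
    """Write a cloud; inverse of :func:`read_cloud` for coordinates, labels
    and normals."""
    if len(cloud) == 0:
        raise EmptyCloudError("refusing to write an empty cloud")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        _write_xyz(cloud, path)
    elif fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    else:
        raise ValueError(f"unknown cloud format: {fmt!r}")


def _read_xyz(path: Path) -> PointCloud:
    pts: list[list[float]] = []
    labels: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise CloudParseError(
                    f"{path}:{lineno}: expected 'x y z [label]', got {raw.rstrip()!r}")
            try:
                pts.append([float(v) for v in parts[:3]])
            except ValueError as exc:
                raise CloudParseError(f"{path}:{lineno}: {exc}") from exc
            if len(parts) == 4:
                tok = parts[3]
                if tok in NAME_TO_LABEL:
                    labels.append(NAME_TO_LABEL[tok])
                else:
                    try:
                        labels.append(int(tok))
                    except ValueError as exc:
                        raise CloudParseError(
                            f"{path}:{lineno}: bad label {tok!r}") from exc
    if not pts:
        raise EmptyCloudError(f"{path}: no points")
    if labels and len(labels) != len(pts):
        raise CloudParseError(f"{path}: label column present on only some lines")
    return PointCloud(np.array(pts), np.array(labels) if labels else None)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(cloud.points):
            line = f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}"
            if cloud.labels is not None:
                line += f" {LABEL_NAMES.get(int(cloud.labels[i]), str(int(cloud.labels[i])))}"
            fh.write(line + "\n")


_PLY_DTYPES = {
    "float": ("<f4", float), "float32": ("<f4", float),
    "double": ("<f8", float), "float64": ("<f8", float),
    "uchar": ("<u1", int), "uint8": ("<u1", int),
    "char": ("<i1", int), "int8": ("<i1", int),
    "short": ("<i2", int), "int16": ("<i2", int),
    "ushort": ("<u2", int), "uint16": ("<u2", int),
    "int": ("<i4", int), "int32": ("<i4", int),
    "uint": ("<u4", int), "uint32": ("<u4", int),
}


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudParseError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []  # (type, name) of the vertex element
        element = None
        while True:
            raw = fh.readline()
            if not raw:
                raise CloudParseError(f"{path}: unexpected EOF in header")
            line = raw.decode("ascii", "replace").strip()
            if line == "end_header":
                break
            parts = line.split()
            if not parts or parts[0] == "comment":
                continue
            if parts[0] == "format":
                fmt = parts[1]
            elif parts[0] == "element":
                element = parts[1]
                if element == "vertex":
                    n_vertex = int(parts[2])
            elif parts[0] == "property" and element == "vertex":
                if parts[1] == "list":
                    raise CloudParseError(f"{path}: list property on vertex element")
                props.append((parts[1], parts[2]))
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudParseError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise CloudParseError(f"{path}: no vertex element")
        if n_vertex == 0:
            raise EmptyCloudError(f"{path}: no points")
        names = [n for _, n in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise CloudParseError(f"{path}: vertex element lacks property {axis!r}")
        if fmt == "ascii":
            rows = []
            for rec in range(n_vertex):
                raw = fh.readline()
                if not raw:
                    raise CloudParseError(f"{path}: vertex record {rec}: unexpected EOF")
                vals = raw.split()
                if len(vals) < len(props):
                    raise CloudParseError(
                        f"{path}: vertex record {rec}: expected {len(props)} values")
                rows.append([float(v) for v in vals[: len(props)]])
            data = {n: np.array([r[i] for r in rows]) for i, (_, n) in enumerate(props)}
        else:
            try:
                dtype = np.dtype([(n, _PLY_DTYPES[t][0]) for t, n in props])
            except KeyError as exc:
                raise CloudParseError(f"{path}: unknown property type {exc}") from exc
            buf = fh.read(dtype.itemsize * n_vertex)
            if len(buf) < dtype.itemsize * n_vertex:
                raise CloudParseError(f"{path}: truncated binary vertex data")
            arr = np.frombuffer(buf, dtype=dtype, count=n_vertex)
            data = {n: np.asarray(arr[n], dtype=np.float64) for _, n in props}
    points = np.column_stack([data["x"], data["y"], data["z"]])
    labels = data["label"].astype(np.int64) if "label" in data else None
    normals = None
    if all(k in data for k in ("nx", "ny", "nz")):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]])
        bad = ~np.isfinite(normals).all(axis=1)
        n = np.linalg.norm(normals, axis=1)
        with np.errstate(invalid="ignore"):
            normals = np.where((n > 0)[:, None], normals / np.where(n > 0, n, 1.0)[:, None], np.nan)
        normals[bad] = np.nan
    return PointCloud(points, labels, normals)


def _write_ply(cloud: PointCloud, path: Path, binary: bool = False) -> None:
    props = [("double", "x"), ("double", "y"), ("double", "z")]
    cols: list[np.ndarray] = [cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]]
    if cloud.normals is not None:
        props += [("double", "nx"), ("double", "ny"), ("double", "nz")]
        cols += [cloud.normals[:, 0], cloud.normals[:, 1], cloud.normals[:, 2]]
    if cloud.labels is not None:
        props.append(("uchar", "label"))
        cols.append(cloud.labels.astype(np.uint8))
    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {len(cloud)}"]
    header += [f"property {t} {n}" for t, n in props]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            dtype = np.dtype([(n, _PLY_DTYPES[t][0]) for t, n in props])
            rec = np.empty(len(cloud), dtype=dtype)
            for (_, n), col in zip(props, cols):
                rec[n] = col
            fh.write(rec.tobytes())
        else:
            for i in range(len(cloud)):
                vals = []
                for (t, _), col in zip(props, cols):
                    v = col[i]
                    vals.append(str(int(v)) if t == "uchar" else f"{float(v):.12g}")
                fh.write((" ".join(vals) + "\n").encode("ascii"))
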