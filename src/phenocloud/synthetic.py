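"""Synthetic barley-like plants with exact ground truth.

Real laser scans of potted cereals are rarely deposited, so every stage of
the pipeline is exercised on generated plants: tillers are sampled on
cylinder coats (radius ~1-4 mm, length 50-400 mm, slightly tilted away from
vertical), leaves on curved ribbon surfaces attached along the upper part of
a stem. The ribbon spine is a parabola re-parameterized by arc length and
extruded flat across the width, so the true leaf area is exactly
``width x length``. Clouds are sampled slightly denser than the target
resolution, perturbed with Gaussian sensor noise, then thinned with the same
greedy routine the pipeline uses — mimicking the homogeneous ~1 mm
resolution of a thinned hand-held scan.

The generator returns, next to the labeled cloud, a :class:`GroundTruth`
with per-stem cylinder parameters, per-leaf analytic areas, per-point organ
identities, and the cumulated totals that the pipeline is supposed to
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cloud import LEAF, STEM, PointCloud, thin_indices

_GOLDEN_DEG = 137.50776405


def _as_list(value, n, name) -> list[float]:
    if np.isscalar(value):
        return [float(value)] * n
    out = [float(v) for v in value]
    if len(out) != n:
        raise ValueError(f"{name}: expected {n} values, got {len(out)}")
    return out


@dataclass(frozen=True)
class PlantSpec:
    """Generative description of one plant at one date.

    Scalar geometry fields broadcast over stems / leaves; sequences give
    per-organ values. Angles in degrees, lengths in mm.
    """

    n_stems: int = 1
    stem_radius: float | Sequence[float] = 2.0
    stem_length: float | Sequence[float] = 150.0
    stem_tilt: float | Sequence[float] | None = None  # default: 6 deg (1 stem) / 16 deg
    stem_azimuth: float | Sequence[float] | None = None  # default: evenly spread
    base_spread: float = 25.0  # radius of the circle the stem bases sit on
    n_leaves: int = 3
    leaf_width: float | Sequence[float] = 8.0
    leaf_length: float | Sequence[float] = 60.0
    leaf_curvature: float = 0.004  # parabola droop coefficient (1/mm)
    leaf_elevation: float = 40.0  # initial climb angle of the leaf spine (deg)
    spacing: float = 1.0  # target point-to-point resolution (mm)
    noise_sigma: float = 0.05  # additive Gaussian sensor noise (mm)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stems < 0 or self.n_leaves < 0:
            raise ValueError("organ counts must be >= 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        tilts = self._tilts()
        if any(t > 45.0 for t in tilts):
            raise ValueError("stem tilt must be <= 45 degrees")

    def _tilts(self) -> list[float]:
        if self.stem_tilt is None:
            return [6.0 if self.n_stems == 1 else 16.0] * self.n_stems
        return _as_list(self.stem_tilt, self.n_stems, "stem_tilt")

    def _azimuths(self) -> list[float]:
        if self.stem_azimuth is None:
            return [360.0 * i / max(self.n_stems, 1) for i in range(self.n_stems)]
        return _as_list(self.stem_azimuth, self.n_stems, "stem_azimuth")


@dataclass
class GroundTruth:
    """Generative parameters aligned with the emitted cloud."""

    stems: list[dict] = field(default_factory=list)   # base, axis, radius, length
    leaves: list[dict] = field(default_factory=list)  # area, width, length, stem
    stem_ids: np.ndarray | None = None   # per-point stem index, -1 for leaf points
    leaf_ids: np.ndarray | None = None   # per-point leaf index, -1 for stem points

    @property
    def n_stems(self) -> int:
        return len(self.stems)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def cumulated_stem_height(self) -> float:
        return float(sum(s["length"] for s in self.stems))

    @property
    def cumulated_leaf_area(self) -> float:
        return float(sum(lf["area"] for lf in self.leaves))


def _unit(v):
    return v / np.linalg.norm(v)


def _stem_axis(tilt_deg: float, az_deg: float) -> np.ndarray:
    t, a = np.radians(tilt_deg), np.radians(az_deg)
    return np.array([np.sin(t) * np.cos(a), np.sin(t) * np.sin(a), np.cos(t)])


def _frame_perp(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(a, ref))
    return e1, np.cross(a, e1)


def _segment_distance(p0, d0, l0, p1, d1, l1) -> float:
    """Minimum distance between two 3D line segments."""
    best = np.inf
    for s in np.linspace(0, l0, 25):
        q = p0 + s * d0
        t = np.clip((q - p1) @ d1, 0, l1)
        best = min(best, float(np.linalg.norm(q - (p1 + t * d1))))
    for t in np.linspace(0, l1, 25):
        q = p1 + t * d1
        s = np.clip((q - p0) @ d0, 0, l0)
        best = min(best, float(np.linalg.norm(q - (p0 + s * d0))))
    return best


def _sample_stem(base, axis, radius, length, pitch, rng):
    """Uniform random sampling of the coat (scanner hits are not gridded);
    density ~1/pitch^2 oversamples the target resolution so that thinning
    leaves a homogeneous, Poisson-disk-like cover."""
    e1, e2 = _frame_perp(axis)
    area = 2 * np.pi * radius * length
    n = max(60, int(np.ceil(1.8 * area / pitch ** 2)))
    h = rng.uniform(0.0, length, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    return (base + h[:, None] * axis
            + radius * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))


def _leaf_spine(attach, az_deg, elevation_deg, curvature, length, n=2048):
    """Arc-length sampled parabolic spine in the vertical plane at az_deg."""
    dh = np.array([np.cos(np.radians(az_deg)), np.sin(np.radians(az_deg)), 0.0])
    slope0 = np.tan(np.radians(elevation_deg))
    xi = np.linspace(0.0, length, n)
    dz = slope0 - 2.0 * curvature * xi
    ds = np.sqrt(1.0 + dz * dz)
    arclen = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2 * np.diff(xi))])
    return dh, xi, arclen, slope0


def _sample_leaf(attach, az_deg, elevation_deg, curvature, width, length, pitch,
                 rng):
    dh, xi_grid, arclen, slope0 = _leaf_spine(attach, az_deg, elevation_deg,
                                              curvature, length)
    n = max(60, int(np.ceil(1.8 * width * length / pitch ** 2)))
    s_vals = rng.uniform(0.0, length, n)
    w_vals = rng.uniform(-width / 2, width / 2, n)
    # explicit blade-margin rails: the outline of a leaf is a sharp edge a
    # scanner does capture, and without it the meshed area shrinks by about
    # half a point spacing all around the blade
    n_edge = max(2, int(np.ceil(length / pitch)) + 1)
    s_edge = np.linspace(0.0, length, n_edge)
    n_wide = max(2, int(np.ceil(width / pitch)) + 1)
    w_edge = np.linspace(-width / 2, width / 2, n_wide)
    # rails first: the greedy thinning pass keeps earlier points, so the
    # blade outline survives thinning
    s_vals = np.concatenate([s_edge, s_edge, np.zeros(n_wide),
                             np.full(n_wide, length), s_vals])
    w_vals = np.concatenate([np.full(n_edge, -width / 2),
                             np.full(n_edge, width / 2), w_edge, w_edge, w_vals])
    s_vals = np.clip(s_vals, 0, arclen[-1])
    xi = np.interp(s_vals, arclen, xi_grid)
    zeta = slope0 * xi - curvature * xi * xi
    spine = attach + xi[:, None] * dh + zeta[:, None] * np.array([0.0, 0.0, 1.0])
    b = np.array([-dh[1], dh[0], 0.0])
    return spine + w_vals[:, None] * b


def generate_plant(spec: PlantSpec) -> tuple[PointCloud, GroundTruth]:
    """Sample a labeled plant cloud plus its generative ground truth.

    Deterministic for a fixed spec (including seed). Raises ``ValueError``
    for impossible geometry (stem axes closer than the sum of radii).
    """
    rng = np.random.default_rng(spec.seed)
    radii = _as_list(spec.stem_radius, spec.n_stems, "stem_radius")
    lengths = _as_list(spec.stem_length, spec.n_stems, "stem_length")
    tilts = spec._tilts()
    azimuths = spec._azimuths()
    widths = _as_list(spec.leaf_width, spec.n_leaves, "leaf_width")
    llengths = _as_list(spec.leaf_length, spec.n_leaves, "leaf_length")

    bases, axes = [], []
    for i in range(spec.n_stems):
        az = np.radians(azimuths[i])
        r_b = 0.0 if spec.n_stems == 1 else spec.base_spread
        bases.append(np.array([r_b * np.cos(az), r_b * np.sin(az), 0.0]))
        axes.append(_stem_axis(tilts[i], azimuths[i]))
    for i in range(spec.n_stems):
        for j in range(i + 1, spec.n_stems):
            d = _segment_distance(bases[i], axes[i], lengths[i],
                                  bases[j], axes[j], lengths[j])
            if d < radii[i] + radii[j]:
                raise ValueError(
                    f"stems {i} and {j} overlap (axis distance {d:.2f} mm "
                    f"< {radii[i] + radii[j]:.2f} mm)")

    pitch = 0.75 * spec.spacing
    truth = GroundTruth()
    chunks, labels, stem_ids, leaf_ids = [], [], [], []
    for i in range(spec.n_stems):
        pts = _sample_stem(bases[i], axes[i], radii[i], lengths[i], pitch, rng)
        chunks.append(pts)
        labels.append(np.full(len(pts), STEM))
        stem_ids.append(np.full(len(pts), i))
        leaf_ids.append(np.full(len(pts), -1))
        truth.stems.append({"base": bases[i], "axis": axes[i],
                            "radius": radii[i], "length": lengths[i]})

    # leaves round-robin over stems, staggered along the upper half of the
    # stem and fanned in azimuth so neighbouring leaves stay separable
    per_stem: dict[int, int] = {}
    for j in range(spec.n_leaves):
        s = j % max(spec.n_stems, 1)
        k = per_stem.get(s, 0)
        per_stem[s] = k + 1
        if spec.n_stems == 0:
            attach = np.array([0.0, 0.0, 10.0 + 30.0 * j])
            az = _GOLDEN_DEG * j
        else:
            n_on_stem = spec.n_leaves // spec.n_stems + (1 if s < spec.n_leaves % spec.n_stems else 0)
            frac = 0.92 - (0.5 * k / max(n_on_stem - 1, 1) if n_on_stem > 1 else 0.0)
            az = azimuths[s] + 60.0 + _GOLDEN_DEG * k
            radial = _stem_axis(90.0, az)
            attach = bases[s] + frac * lengths[s] * axes[s] + radii[s] * radial
        pts = _sample_leaf(attach, az, spec.leaf_elevation, spec.leaf_curvature,
                           widths[j], llengths[j], pitch, rng)
        chunks.append(pts)
        labels.append(np.full(len(pts), LEAF))
        stem_ids.append(np.full(len(pts), -1))
        leaf_ids.append(np.full(len(pts), j))
        truth.leaves.append({"area": widths[j] * llengths[j], "width": widths[j],
                             "length": llengths[j], "stem": s})

    if not chunks:
        raise ValueError("spec generates no points (no stems and no leaves)")
    pts = np.vstack(chunks)
    labels = np.concatenate(labels)
    stem_ids = np.concatenate(stem_ids)
    leaf_ids = np.concatenate(leaf_ids)
    if spec.noise_sigma > 0:
        pts = pts + rng.normal(0.0, spec.noise_sigma, pts.shape)
    kept = thin_indices(pts, spec.spacing)
    truth.stem_ids = stem_ids[kept]
    truth.leaf_ids = leaf_ids[kept]
    return PointCloud(pts[kept], labels[kept]), truth


def generate_time_course(
    base: PlantSpec,
    n_dates: int,
    growth_rates: Mapping[str, float] | None = None,
    stem_additions: Mapping[int, int] | None = None,
    leaf_additions: Mapping[int, int] | None = None,
) -> list[tuple[int, PointCloud, GroundTruth]]:
    """Grow a plant over ``n_dates`` dates.

    ``growth_rates`` are per-date multipliers for ``stem_length``,
    ``leaf_length`` and ``leaf_width`` (default 1.08 / 1.07 / 1.02); organs
    added at date ``d`` (``stem_additions`` / ``leaf_additions``) start at
    the base size and grow from their birth date on. Each date is sampled
    with its own derived seed, so repeated runs are deterministic.
    """
    if n_dates < 2:
        raise ValueError("a time course needs at least 2 dates")
    rates = {"stem_length": 1.08, "leaf_length": 1.07, "leaf_width": 1.02}
    if growth_rates:
        rates.update(growth_rates)
    stem_additions = dict(stem_additions or {})
    leaf_additions = dict(leaf_additions or {})
    base_lengths = _as_list(base.stem_length, base.n_stems, "stem_length")
    base_radii = _as_list(base.stem_radius, base.n_stems, "stem_radius")
    base_llen = _as_list(base.leaf_length, base.n_leaves, "leaf_length")
    base_lwid = _as_list(base.leaf_width, base.n_leaves, "leaf_width")
    stem_birth = [0] * base.n_stems
    leaf_birth = [0] * base.n_leaves
    out = []
    for d in range(n_dates):
        if d > 0:
            stem_birth += [d] * stem_additions.get(d, 0)
            leaf_birth += [d] * leaf_additions.get(d, 0)
        n_s, n_l = len(stem_birth), len(leaf_birth)
        lengths = [
            (base_lengths[i] if i < base.n_stems else base_lengths[0])
            * rates["stem_length"] ** (d - stem_birth[i])
            for i in range(n_s)
        ]
        radii = [base_radii[i] if i < base.n_stems else base_radii[0]
                 for i in range(n_s)]
        llen = [
            (base_llen[i] if i < base.n_leaves else base_llen[0])
            * rates["leaf_length"] ** (d - leaf_birth[i])
            for i in range(n_l)
        ]
        lwid = [
            (base_lwid[i] if i < base.n_leaves else base_lwid[0])
            * rates["leaf_width"] ** (d - leaf_birth[i])
            for i in range(n_l)
        ]
        spec_d = replace(
            base, n_stems=n_s, n_leaves=n_l, stem_length=lengths,
            stem_radius=radii, leaf_length=llen, leaf_width=lwid,
            stem_tilt=None if base.stem_tilt is None or np.isscalar(base.stem_tilt)
            else None,
            stem_azimuth=None,
            seed=base.seed + 101 * d,
        )
        cloud, truth = generate_plant(spec_d)
        out.append((d, cloud, truth))
    return out


def example_course(treatment: str = "irrigated", seed: int = 0,
                   n_dates: int = 10) -> list[tuple[int, PointCloud, GroundTruth]]:
    """Canned 10-date course emulating a well-watered vs. drought-stressed
    tillering trajectory (1 stem / 3 leaves growing to 3 stems / 8 leaves
    for the irrigated plant, slower growth and less tillering when stressed),
    scaled to desk-size clouds."""
    base = PlantSpec(n_stems=1, stem_radius=1.5, stem_length=60.0,
                     n_leaves=3, leaf_width=7.0, leaf_length=40.0,
                     seed=seed)
    if treatment == "irrigated":
        return generate_time_course(
            base, n_dates,
            growth_rates={"stem_length": 1.09, "leaf_length": 1.08, "leaf_width": 1.02},
            stem_additions={3: 1, 6: 1},
            leaf_additions={2: 1, 4: 1, 6: 1, 7: 1, 8: 1},
        )
    if treatment == "stressed":
        return generate_time_course(
            base, n_dates,
            growth_rates={"stem_length": 1.05, "leaf_length": 1.045, "leaf_width": 1.01},
            stem_additions={4: 1},
            leaf_additions={3: 1, 6: 1},
        )
    raise ValueError(f"unknown treatment {treatment!r}")
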