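"""End-to-end orchestration: cloud -> organ labels -> per-organ parameters.

One date's cloud flows through classification (histograms + SVM), region
growing, leaf meshing (area) and stem analysis (direction voting -> count,
single-linkage clustering, RANSAC cylinder fit, length), ending in a
:class:`PlantRecord` with the two tracked totals: cumulated leaf area (sum
of per-leaf mesh areas) and cumulated stem height (sum of per-stem cylinder
lengths, within the date). A time course is simply one record per date.

Partial failures stay local: a stem cluster with fewer than six points is
counted but reported unparameterized, an unmeshable leaf fragment is
skipped, and a date with no stem points yields zero cumulated height while
the leaves are still processed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import OrganClassifier, classify, region_grow_refine
from .cloud import LEAF, STEM, PointCloud
from .cylinder import estimate_length, fit_ransac
from .errors import ConfigError, DegenerateGeometryError, EmptyCloudError, FitError
from .features import FeatureParams, all_histograms, estimate_normals
from .leaves import cumulated_leaf_area, mesh_leaf, segment_leaves
from .stems import cluster_stems, count_stems, vote_directions


@dataclass
class PipelineConfig:
    """All stage parameters in one place; defaults follow the static
    thresholds the method was designed with (1 mm resolution, r_N = 3 mm,
    r_H = 15 mm, 1000 fits per octant on a 10-degree grid with a 20%
    threshold, 50 six-point RANSAC iterations, 0.5 mm coat tolerance)."""

    resolution: float = 1.0         # mm, cloud thinning spacing
    r_N: float = 3.0                # mm, normal-estimation radius
    r_H: float = 15.0               # mm, histogram radius
    bins_per_feature: int = 5
    connect_radius: float = 2.0     # mm, region-growing connectivity
    min_region: int = 50            # points, region-growing size threshold
    leaf_connect_radius: float = 3.0
    leaf_min_points: int = 20
    mesh_max_edge: float = 3.0      # mm
    fits_per_octant: int = 1000
    step_deg: float = 10.0
    threshold_frac: float = 0.20
    ransac_iters: int = 50
    ransac_sample: int = 6
    inlier_tol: float = 1.0         # mm, RANSAC scoring band
    coat_tol: float = 0.5           # mm, length-elongation coat range
    slab: float = 2.0               # mm, elongation step
    min_slab_points: int = 2
    seed: int = 0

    def feature_params(self) -> FeatureParams:
        return FeatureParams(self.r_N, self.r_H, self.bins_per_feature)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PlantRecord:
    """Per-date parameter set."""

    date_id: int | str
    n_stems: int
    n_leaves: int
    cumulated_leaf_area: float      # mm^2
    cumulated_stem_height: float    # mm
    stems: list[dict] = field(default_factory=list)
    leaves: list[dict] = field(default_factory=list)
    n_points: int = 0
    n_stem_points: int = 0
    n_leaf_points: int = 0
    labels: np.ndarray | None = field(default=None, repr=False)


def train_from_cloud(cloud: PointCloud, config: PipelineConfig | None = None,
                     hyper_search: bool = False) -> OrganClassifier:
    """Train the organ SVM from one manually labeled cloud (the reference
    workflow: label a single late date by hand, apply to the whole course)."""
    from .classify import train

    if cloud.labels is None:
        raise ValueError("training requires a labeled cloud")
    config = config or PipelineConfig()
    params = config.feature_params()
    with_normals = estimate_normals(cloud, config.r_N)
    hists = all_histograms(with_normals, params)
    return train(hists, cloud.labels, hyper_search=hyper_search,
                 feature_params=params)


def run_pipeline(cloud: PointCloud, model: OrganClassifier,
                 config: PipelineConfig | None = None,
                 date_id: int | str = 0) -> PlantRecord:
    """Classify, refine and parameterize one plant cloud."""
    if len(cloud) == 0:
        raise EmptyCloudError("cannot run the pipeline on an empty cloud")
    config = config or PipelineConfig()
    params = config.feature_params()
    if getattr(model, "n_features_in_", params.n_bins) != params.n_bins:
        raise ConfigError(
            f"model expects {model.n_features_in_} histogram bins, "
            f"config produces {params.n_bins}")
    if model.feature_params is not None and model.feature_params != params:
        raise ConfigError(
            f"model was trained with {model.feature_params}, "
            f"config requests {params}")

    with_normals = estimate_normals(cloud, config.r_N)
    hists = all_histograms(with_normals, params)
    labels = classify(model, hists)
    refined = region_grow_refine(cloud.with_labels(labels),
                                 config.connect_radius, config.min_region)
    labels = refined.labels

    record = PlantRecord(date_id, 0, 0, 0.0, 0.0,
                         n_points=len(cloud), labels=labels)

    # leaves: segment, mesh, sum areas
    leaf_cloud = cloud.select(labels == LEAF)
    record.n_leaf_points = len(leaf_cloud)
    meshes = []
    for leaf_id, idx in enumerate(segment_leaves(
            leaf_cloud, config.leaf_connect_radius, config.leaf_min_points)):
        entry = {"leaf_id": leaf_id, "n_points": int(len(idx))}
        try:
            mesh = mesh_leaf(leaf_cloud.select(idx), config.mesh_max_edge)
            entry["area_mm2"] = mesh.area
            meshes.append(mesh)
        except DegenerateGeometryError as exc:
            entry["area_mm2"] = None
            entry["error"] = str(exc)
        record.leaves.append(entry)
    record.n_leaves = len(record.leaves)
    record.cumulated_leaf_area = cumulated_leaf_area(meshes)

    # stems: count by direction voting, cluster, fit cylinders
    stem_cloud = cloud.select(labels == STEM)
    record.n_stem_points = len(stem_cloud)
    if len(stem_cloud) >= 5:
        acc = vote_directions(stem_cloud, config.fits_per_octant,
                              config.step_deg, seed=config.seed)
        k, _ = count_stems(acc, config.threshold_frac)
        k = max(1, min(k, len(stem_cloud) // config.ransac_sample or 1))
        clusters = cluster_stems(stem_cloud, k)
        record.n_stems = clusters.k
        for stem_id in range(clusters.k):
            pts = stem_cloud.points[clusters.assignment == stem_id]
            entry = {"stem_id": stem_id, "n_points": int(len(pts))}
            if len(pts) < config.ransac_sample:
                entry["parameterized"] = False
                record.stems.append(entry)
                continue
            try:
                sol = fit_ransac(pts, config.ransac_iters, config.ransac_sample,
                                 seed=config.seed + stem_id,
                                 inlier_tol=config.inlier_tol)
                cyl = estimate_length(sol.cylinder, pts, config.coat_tol,
                                      config.slab, config.min_slab_points)
                entry.update(parameterized=True,
                             P=cyl.point.tolist(), a=cyl.axis.tolist(),
                             r_mm=cyl.radius, length_mm=cyl.length,
                             converged=sol.converged,
                             rms_residual=sol.rms_residual)
                record.cumulated_stem_height += cyl.length or 0.0
            except (FitError, DegenerateGeometryError) as exc:
                entry["parameterized"] = False
                entry["error"] = str(exc)
            record.stems.append(entry)
    return record


def run_time_course(clouds: list[tuple[int | str, PointCloud]],
                    model: OrganClassifier,
                    config: PipelineConfig | None = None) -> list[PlantRecord]:
    """One record per (date, cloud), sorted by date."""
    if not clouds:
        raise ValueError("a time course needs at least one date")
    records = [run_pipeline(c, model, config, date_id=d)
               for d, c in sorted(clouds, key=lambda dc: dc[0])]
    return records


def records_to_frame(records: list[PlantRecord]) -> pd.DataFrame:
    """Tabular view of a time course (one row per date)."""
    return pd.DataFrame([{
        "date": r.date_id,
        "n_points": r.n_points,
        "stem_points": r.n_stem_points,
        "leaf_points": r.n_leaf_points,
        "stems": r.n_stems,
        "leaves": r.n_leaves,
        "cumulated_leaf_area_mm2": r.cumulated_leaf_area,
        "cumulated_stem_height_mm": r.cumulated_stem_height,
    } for r in records])
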