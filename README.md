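# phenocloud

Organ-level phenotyping of cereal plants from 3D laser-scan point clouds.

Breeders and plant scientists who scan single potted plants (barley, wheat,
rice) with a hand-held laser scanner get millions of unlabeled XYZ points.
Tracking extension growth requires splitting each scan into its functional
organs — leaves and stems — and reducing each organ to a few numbers: the
leaf area and the stem (tiller) height. Doing that by hand takes hours per
plant; `phenocloud` automates the whole chain so a dated series of scans
turns into a growth table.

## Method

Given a cloud thinned to a homogeneous ~1 mm resolution:

1. **Surface feature histograms.** Each point gets a normal **n** by PCA
   over its r_N = 3 mm neighbourhood. For a point and each neighbour within
   r_H = 15 mm, the Darboux-frame angles are computed from the source
   normal **u** = **n**_s, **v** = **u** × **t**, **w** = **u** × **v**
   (with **t** the unit translation between the points):
   α = **v**·**n**_t, φ = **u**·**t**, θ = atan2(**w**·**n**_t, **u**·**n**_t).
   The joint (α, φ, θ) histogram with 5 bins per feature — 125 bins, unit
   sum — describes the local surface: thin cylinders (stems) and
   near-planar ribbons (leaves) are clearly separable.
2. **Classification.** An RBF-kernel SVM trained on one manually labeled
   plant labels every point leaf or stem; region growing then absorbs small
   connected label regions into their dominant neighbour, removing
   salt-and-pepper errors.
3. **Stem counting and clustering.** The stem points (centered at their
   center of gravity) are split into the eight octants; in each, 1000
   five-point line fits vote their principal direction into a spherical
   accumulator over azimuth φ ∈ [0°, 360°) × polar angle ω ∈ [0°, 180°] in
   10° bins. Thresholding at 20% of the maximum bin leaves one connected
   region per tiller; the region count k fixes the cut of a single-linkage
   Euclidean clustering that separates the individual stems.
4. **Cylinder parameterization.** Each stem cluster is adjusted to the
   implicit cylinder model Φ_i = ‖(**P** − **Q**_i) × **a**‖ − r = 0 under
   the restrictions γ = (‖**a**‖, z_p) = (1, h) — a restricted
   Gauss–Helmert least-squares problem solved by iterated linearization
   (A Δx + B v + w₁ = 0, C Δx = −w₂), started from the cluster centroid and
   the upright axis (0,0,1)ᵀ. Robustness against misclassified points comes
   from 50 RANSAC iterations over six-point minimal subsets; the cylinder
   length follows by elongating the axis while cluster points stay within
   0.5 mm of the coat.
5. **Leaf parameterization.** Each connected leaf segment is flattened
   isometrically (leaves are near-developable ribbons), triangulated, and
   its area summed over triangles.

Per date this yields a `PlantRecord` with the stem count, leaf count,
**cumulated leaf area** (Σ leaf mesh areas) and **cumulated stem height**
(Σ cylinder lengths); a time course is one record per measuring date.

Because real scans of this kind are rarely published, the package ships a
synthetic-plant generator (`phenocloud.synthetic`) producing labeled
barley-like clouds — tilted cylindrical tillers plus curved ribbon leaves,
1 mm resolution, 0.05 mm sensor noise — with exact analytic ground truth
for every downstream stage.

## Worked example

```python
from phenocloud import (PlantSpec, generate_plant, train_from_cloud,
                        run_pipeline, records_to_frame, evaluate)

# one labeled plant stands in for the hand-labeled training scan
train_cloud, _ = generate_plant(PlantSpec(
    n_stems=3, stem_radius=[1.5, 2.0, 2.5], stem_length=[100, 120, 90],
    n_leaves=7, leaf_length=55, leaf_width=8, seed=42))
model = train_from_cloud(train_cloud)

cloud, truth = generate_plant(PlantSpec(
    n_stems=2, stem_radius=2.0, stem_length=100,
    n_leaves=4, leaf_length=55, leaf_width=8, seed=31))
record = run_pipeline(cloud, model)
print(records_to_frame([record]).to_string(index=False))
print(f"weighted accuracy: {evaluate(record.labels, cloud.labels).weighted_accuracy:.1f}%")
```

prints

```
 date  n_points  stem_points  leaf_points  stems  leaves  cumulated_leaf_area_mm2  cumulated_stem_height_mm
    0      2383         1332         1051      2       4              1747.438767                199.902571
weighted accuracy: 99.5%
```

Both tillers and all four leaves were found; the cumulated leaf area
(1747 mm² vs. 1760 mm² generative truth) and cumulated stem height
(199.9 mm vs. 200 mm) are recovered to within about 1%.

The same pipeline is available from the shell
(`phenocloud simulate/train/classify/run/course`); `phenocloud course`
turns a manifest of dated clouds into a `records.csv` growth table.

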