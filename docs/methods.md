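# Methods

This note records the models, parameter choices and numerical decisions
behind `phenocloud`, and what the synthetic experiments do and do not show.

## Point clouds and thinning

All coordinates are millimetres; no unit autodetection is attempted. Scans
from hand-guided scanners have wildly varying density, so every pipeline
entry point first thins the cloud to a homogeneous resolution (default
minimum point-to-point distance 1 mm). Thinning is a greedy pass in input
order over a voxel hash: a point is kept iff no previously kept point lies
within the spacing. This keeps original points (no resampling), is O(n),
deterministic, idempotent, and guarantees the pairwise minimum distance
exactly. I/O covers XYZ text (`x y z [label]`, `#` comments) and PLY
(ascii and binary_little_endian; vertex properties x, y, z, optional
`uchar label`, optional nx, ny, nz).

## Surface feature histograms

The per-point descriptor bins the Darboux-frame angles between a point and
every neighbour within r_H. The frame convention is the classical
point-feature-histogram one: with unit translation **t** from source to
target, u = n_s, v = u × t (normalized), w = u × v, and features
α = v·n_t ∈ [−1, 1], φ = u·t ∈ [−1, 1], θ = atan2(w·n_t, u·n_t) ∈ (−π, π].
The point whose normal makes the smaller angle with the translation is
taken as the source, which makes the triple symmetric in the pair. The
translation length is computed (it drives the source selection) but not
binned: three features × 5 equal-width bins give the 125-bin joint
histogram, normalized to unit sum. Points with fewer than 3 neighbours
inside r_N, or without any valid-normal neighbour inside r_H, carry an
all-zero histogram flagged invalid and are classified `unknown`.

Defaults r_N = 3 mm and r_H = 15 mm are the static radii the method was
calibrated with for barley at 1 mm resolution (r_N small enough to resolve
a 1.5–2.5 mm stem's curvature, r_H the size of the largest object); both
are configurable. Normals are signed toward a fixed viewpoint high above
the plant; any consistent rule works since all features are relative.

Histograms are invariant under rigid motion and — up to floating-point
summation order — under point reordering; a pair feature lying within
machine epsilon of a bin edge may hop one bin when the summation order
changes, which the tests allow for.

## Classification and region growing

An RBF-kernel SVM (scikit-learn SVC) is trained on the histograms of one
labeled plant; defaults C = 10, gamma = "scale", optionally a grid search
over C ∈ {1, 10, 100}, γ ∈ {0.1, 1, 10} with stratified 5-fold CV. The
trained model records its feature configuration and refuses clouds
processed with a different one.

Region growing removes speckle: connected same-label components of the
2 mm radius graph smaller than 50 points are relabeled to the majority
label of their boundary neighbours (ties toward the largest adjacent
region), repeated until stable. The thresholds are heuristic — 2 mm is
twice the cloud resolution, and 50 points is well below any real organ at
1 mm sampling (a short leaf has several hundred) — and configurable.
Accuracy is reported per class as recall, plus the point-count-weighted
mean over classes.

## Stem counting, clustering

Stem axes are found by repeated minimal line fits: the stem-labeled cloud
is centered at its center of gravity and split into the eight octants; in
each octant with at least five points, 1000 five-point subsets are drawn
and the principal direction of each is binned on the sphere (azimuth ×
polar angle, 10° steps). Line directions are sign-ambiguous, so they are
canonicalized to the upper hemisphere before binning — stems grow upward,
and without this every tiller would produce two antipodal maxima. The
accumulator is thresholded at 20% of its maximum bin (the paper-style
threshold interpreted as max-bin fraction); connected regions are counted
8-connected with azimuth wraparound, and all set bins of the polar-cap row
are merged since they represent nearly identical near-vertical directions.
Voting runs on the stem-labeled subset when a classification is available.

The region count k then cuts a single-linkage Euclidean hierarchy into the
per-stem clusters. For large clouds the equivalent minimum-spanning-tree
formulation (drop the k−1 largest MST edges, computed from the Delaunay
edge set) avoids the dense distance matrix; tests verify the two routes
produce identical partitions.

Counting stems by direction requires the tillers to differ in direction by
more than one bin; the generator therefore tilts multiple stems ~16° from
vertical at spread azimuths, which matches how tillers fan out of a pot.
Two stems with near-identical directions would merge into one region —
a known limitation of direction voting.

## Restricted Gauss–Helmert cylinder adjustment

The cylinder is the implicit condition Φ_i = ‖(P − Q_i) × a‖ − r = 0 with
seven parameters (axis point P, axis a, radius r) and two gauge
restrictions ‖a‖ = 1 and z_p = h; h is fixed to the cluster centroid's z,
keeping the axis point inside the data. Each iteration evaluates
A = ∂Φ/∂x, B = ∂Φ/∂Q and C = ∂γ/∂x at the current parameters and adjusted
observations, forms the misclosures w₁ = Φ − Bv and w₂ = γ − (1, h), and
solves the bordered normal system

    [ Aᵀ(BBᵀ)⁻¹A  Cᵀ ] [Δx]   [ −Aᵀ(BBᵀ)⁻¹w₁ ]
    [ C           0  ] [k ] = [ −w₂          ]

with the observation corrections recovered by back-substitution. Because B
rows here have unit norm (the axis is unit and Φ is a true Euclidean
distance), the adjustment minimizes the sum of squared orthogonal
distances to the coat. Convergence: parameter-update norm < 1e-8, at most
100 iterations; steps that would drive the radius non-positive are halved
(minimal six-point systems overshoot in early iterations). After
convergence the two restrictions are re-imposed exactly by renormalizing
the axis and sliding P along it — a pure re-parameterization. Start
values: centroid for P, upright (0, 0, 1)ᵀ for a (cereal stems grow up),
mean point-to-axis distance for r. Minimal six-point problems are
multi-modal and occasionally converge to a non-global stationary point;
inside RANSAC such candidates simply score badly and are discarded.

RANSAC draws 50 six-point subsets; each converged candidate is scored by
the truncated squared-residual sum over all cluster points (saturating at
the 1 mm inlier band, so out-of-band points pay a constant penalty and a
candidate cannot win by shrinking its inlier set), and the best candidate
is refined on its inliers. The length is then found by elongation: cluster
points within 0.5 mm of the coat are projected on the axis and an interval
growing in 2 mm slabs from the median coat point extends while each new
slab holds at least 2 coat points; the length is the axial span of the
accepted coat points. The slab/min-point defaults were chosen for thin
tillers at 1 mm resolution (~5–9 coat points per mm of axis): demanding
3 points inside a 1 mm slab terminates on ordinary sampling fluctuations.
A ≥ 2 mm sampling gap (occlusion) stops the elongation — the reported
length is then the covered span, not the true organ length. Clusters with
fewer than six points are counted but left unparameterized.

## Leaf meshing

Leaf segments are connected components of the 3 mm radius graph over
leaf-labeled points; fragments under 20 points are discarded. Each segment
is meshed by isometric unrolling: Isomap (geodesic distances over the
neighbour graph) embeds the points in the plane — exact up to sampling
error for developable surfaces, which grass leaves approximate well — and
one global 2D Delaunay triangulation of the embedding is lifted back to
3D. Triangles with any 3D edge over 3 mm (three times the sampling pitch)
are dropped, which trims convex-hull fill outside the true outline; holes
from occlusion stay open, so the reported area is the meshed area. On
analytic fixtures the area is exact for a sampled rectangle and within
0.1% for a half-cylinder ribbon. Leaf blade and sheath are not
distinguished.

## Synthetic plants

The generator emulates the study conditions: 1–4 cylindrical tillers
(radius 1.5–2.5 mm, length 50–400 mm, single stems tilted ~6°, multiple
stems ~16° at spread azimuths, bases on a 25 mm circle), 2–15 leaves as
parabolic-spine ribbons (width 5–15 mm, length 40–300 mm) attached along
the upper half of a stem and fanned by the golden angle; surfaces are
sampled uniformly at random ~1.8× denser than the 1 mm target and thinned
with the pipeline's own routine, after adding 0.05 mm Gaussian sensor
noise (the scanner accuracy class). The ribbon spine is arc-length
parameterized, so the true leaf area is exactly width × length; stem truth
is the generating cylinder. Leaf outlines are sampled explicitly (rails
first, so thinning keeps them): without them the meshed area of a narrow
ribbon is biased low by about half a spacing all around the margin.

Time courses grow stem lengths and leaf dimensions geometrically per date
(defaults 8%/7%/2% per date) and add tillers/leaves at configurable dates;
`example_course` provides a canned 10-date pair of trajectories — a
well-watered plant tillering to 3 stems / 8 leaves and a slower, less
tillering drought-stressed one — scaled to desk-size clouds (~800–4000
points per date) so a full two-treatment course runs in well under a
minute.

What the fixtures do **not** emulate: occlusion and self-shadowing,
registration artefacts between scan sweeps, leaf rolling and twisting,
ears, and the gradual leaf/stem transition at the sheath. Classification
accuracy on these clean surfaces (~99%) is therefore an upper bound, not a
prediction for real scans, where the stem class is hardest near that
transition; the structural claims (counts, cylinder and area recovery,
monotone growth tracking, treatment contrast) are the transferable part.

## Degenerate inputs and edge cases

Empty clouds, single-class training sets, clusters below the minimal
sample, collinear point sets and points on the fitted axis raise typed
errors (`EmptyCloudError`, `DegenerateGeometryError`, `FitError`,
`ConfigError`); sparse points get flagged (invalid normal/histogram,
`unknown` label) rather than aborting a run. Pipeline runs are
deterministic given the config seed: voting, RANSAC and the generator all
derive their randomness from explicit seeds.
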