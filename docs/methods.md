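# Methods

This note records the models, conventions and numerical choices behind
`teabud3d`, and what its synthetic benchmark does and does not establish.
All geometry is in dimensionless scene units (monocular reconstruction is
scale-ambiguous; no metric scale is claimed); the z axis is vertical.

## The synthetic world

The generator emulates the point cloud obtained by sampling a semantic
radiance field of a tea tree. Its components:

- **Foliage shell.** `foliage_points` samples on the upper hemisphere of
  radius `canopy_radius` with 2% radial thickness — surface-concentrated,
  high density (σ ∈ [0.5, 1]), low bud probability (≤ 0.2). Radiance-field
  densities concentrate near surfaces, so all solid structure is sampled on
  surfaces, not in volumes.
- **Buds.** `n_buds` prolate ellipsoids with equatorial semi-axis
  r ~ N(0.01, 0.0015) (floored at 0.5× the mean) and polar semi-axis
  r × `bud_elongation` (default 5: a young "single bud" tea shoot is
  several times taller than wide). The bud axis deviates from vertical by a
  uniform tilt up to `bud_tilt_max_deg` (default 30°), so obliquely growing
  buds occur. The lower axis end is attached to the canopy surface; the
  **basal point** is that attachment-end surface point as emitted in the
  cloud (its sample is pinned and always survives occlusion dropout — the
  attachment is where the bud meets the branch), and the **basal normal**
  is the bud axis. Bud points carry σ ∈ [0.6, 1] and bud probability
  ∈ [0.9, 1].
- **Sampling density.** `points_per_bud` (default 2400) is the count for a
  mean-size bud; actual counts scale with surface area so that point
  spacing is uniform across bud sizes, as a field sampled on a uniform
  spatial grid would give. This matters: the normal-consistency constraint
  (below) is satisfiable only where the spacing is ≲ 0.15× the local
  curvature radius, and a constant per-bud count would leave large buds
  under-sampled relative to a density-adaptive eps.
- **Floaters.** A fraction of points placed along segments from a ring of
  camera-like viewpoints to bud centers, with high bud probability
  (≥ 0.9) but low density (σ ∈ [0.05, 0.4]) — the line-of-sight semantic
  leakage artifact that density gating removes. Every floater sits strictly
  below the σ = 0.45 gate by construction.
- **Perturbations.** Bernoulli occlusion dropout per bud point and
  isotropic Gaussian jitter (`noise_sd`, default 0.001) on all points.
  Channel values are drawn before the dropout subset so the random stream —
  and hence all bud geometry — is identical across dropout rates at a fixed
  seed.
- **Placement.** Bud attachments are rejection-sampled on the canopy with a
  minimum spacing of 1.2× the mean bud length. Slender tilted buds can
  physically overlap at smaller spacings; this default keeps the stated
  "well-separated" world actually separable.

What a green test on this world establishes: the geometric pipeline
(filtering → constrained clustering → merging → counting → picking) recovers
the generator's parameters under its stated noise. What it does not: real
radiance-field clouds have anisotropic, view-dependent noise, partial
surfaces, leaves touching buds, and non-ellipsoidal bud shapes; none of
these is modeled, so real-data performance is out of scope here.

## Semantic filtering

`dsc_filter` keeps points with σ ≥ `sigma_min` (default 0.45, inclusive) as
the tree cloud and, of those, points with bud probability ≥ `prob_min`
(default 0.5 — the maximum-probability rule for a binary field; no external
source) as the bud cloud. Order is preserved; the filter is idempotent.
Statistical outlier removal computes each point's mean distance to its k
nearest neighbors (k = 16 by default) and drops points above the global
mean + `std_ratio` × sd (population sd); radius outlier removal requires
`min_neighbors` other points within `radius`. Both are single-pass. The
pipeline applies them in the order statistical → radius by default
(configurable; no external ordering is specified).

## Clustering and counting

- **Normals**: smallest-eigenvalue eigenvector of the k-NN covariance
  (k = 12), sign-fixed to non-negative z (ties: +x, then +y). Eigenvector
  signs are arbitrary, so all angle comparisons are orientation-insensitive.
- **Adaptive eps**: median over points of the k-th-NN distance (k = 8)
  × 1.5. A single global radius; the factor and k are engineering defaults.
- **Constrained DBSCAN**: neighbors must satisfy distance ≤ eps **and**
  angle(n_i, n_j) ≤ clamp (default 15°), with angle = arccos|n_i·n_j|.
  Core points have ≥ `min_pts` (default 8) such neighbors including
  themselves. The expansion replicates the classic index-ordered stack
  algorithm, so with the constraint disabled (clamp 180°) the labels equal
  standard DBSCAN implementations exactly, border-point assignment
  included. The constraint is applied at the neighborhood-edge level, not
  as post-hoc cluster splitting.
- **Merging**: clusters whose centroids are strictly closer than
  `avg_bud_radius` are linked; connected components merge (transitive
  closure), with centroid and hull volume recomputed from the union.
  `avg_bud_radius` is read as the spatial radius of a whole bud (default
  0.05 = mean half-length in the synthetic world), since the rule exists to
  reunite fragments of one bud — a stem-radius-scale value could never
  reach across a bud. The constrained DBSCAN necessarily fragments
  high-curvature apex caps (where any clamp is violated at finite
  sampling); merging and the volume filter reabsorb or discard those
  fragments.
- **Volume filter**: convex-hull volume (degenerate hulls count 0); drop
  clusters below `min_volume_fraction` (default 0.1) × median volume.

Known limitation: the transitive merge can chain across two genuinely
distinct buds whose fragments interleave; on the synthetic world this
appears only when buds are placed closer than the default spacing, and is
exactly the under-counting failure mode that dense bud regions cause on
real trees.

## Candidate picking points

The basal subset is the lowest 5% of a cluster's z **range** (not a point
count quantile — "height range" — though the count-quantile variant is
available as `basal_mode="count_quantile"`). RANSAC (default 100
iterations, inlier distance 0.005, seeded) fits a plane to it; the fit is
degenerate with < 3 points, all-collinear samples, or inlier ratio < 0.2.
Plane normals are re-oriented to non-positive z ("downward"), making
"the negative normal direction" unambiguous.

Two strategies: `plane_center` (default) projects the inlier centroid onto
the plane; `min_projection` selects the basal-extreme inlier along the
plane normal — the smallest projection onto the upward normal, ties broken
by smallest index. The single-point extreme is inherently more sensitive to
perturbations (its error grows with the flat extent of the basal region on
tilted buds), which is why the plane center is the default; both recover
the true basal point far better than the cluster centroid. Degenerate fits
fall back to the basal-subset centroid (the "estimated local center") and
carry no plane normal.

Offsets displace a candidate by dk × `base_unit` along the downward normal;
the base unit is not externally specified and defaults to `ransac_dist`.
When a repetition's fit is degenerate, the offset variant keeps the
fallback position unoffset rather than erroring.

## Stability protocol

p = 5 repetitions; each draws ⌈ratio × n⌉ points without replacement
(ratio 0.5) with a derived seed (protocol seed + repetition index), adds
optional Gaussian noise, and re-runs the method. µ_p and p90_p are defined
on the pairwise distances of the p estimates (p90 with linear
interpolation); the pass rate is the fraction of estimates strictly within
`tolerance` of their arithmetic mean (geometric-median reference available;
the tolerance default 0.01 has no external source and is reported with
results). Scene rows are unweighted means over clusters.

## Depth reliability

Pinhole projection u = fx·X/Z + cx, v = fy·Y/Z + cy in the camera frame;
visibility requires Z > 0 and the pixel inside the image. Scale alignment
is the median of per-sample ref/pred ratios (the common robust estimator
for scale-ambiguous depth; ratio-of-medians is flag-selectable). The scale
is estimated once on all samples and reused per region — a per-region
rescale would absorb exactly the regional bias the analysis is meant to
expose. AbsRel = mean |pred−ref|/ref, RMSE = √mean (pred−ref)², p90-AbsRel
with linear interpolation. Empty regions report n = 0 with missing
statistics.

## Box and loss math

Inner-IoU shrinks both boxes about their centers by ratio r and takes the
IoU of the shrunk boxes. Each linear overlap extent is clamped below at 0
(the printed intersection formula can otherwise go negative for disjoint
inner boxes), and the inner areas are computed from the same edge
differences as the intersection so identical boxes give exactly 1. Image
convention: y grows downward; boxes are continuous reals. The training
ratio r is not externally specified; the CSV evaluator defaults to r = 0.75
and flags it as unverified. Average precision is the literal discrete sum
Σ P(R_i)ΔR_i with R_0 = 0 (one class, so mAP = AP); an all-point
interpolated variant is available behind a flag for comparison with
mainstream detector tooling.

The semantic loss is standard negative binary cross-entropy (the positive,
minimizable form), with predictions clipped to [1e−7, 1−1e−7] before logs.
The photometric term sums squared error over the 3 channels and averages
over rays; the depth term is a mean L1. Weights λ_sem, λ_depth default to
1.0 and 0.1 and are unverified configuration (no external values are
available).

## Reproducibility

Every stochastic step takes an explicit seed; the pipeline's global seed
fans out as scene = seed, picking = seed + 1000, stability = seed + 2000.
Geometry is float64 internally; PLY stores float32 positions (format
convention). Identical (spec, seed) gives byte-identical PLY output, and
the resolved configuration written next to each run re-runs to identical
artifacts.
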