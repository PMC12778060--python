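# Methods

## The geometric complexity space

`fractalmorph` measures binary 2-D silhouettes of organisms (or simulated
biomorphs) with four fractal descriptors:

- **D_SI** — box-counting dimension of the silhouette: density of body
  mass, from 1 (a filament) to 2 (a solid cell).
- **D_SK** — box-counting dimension of the topological skeleton: density
  of internal structure (number/spread of appendages and branches).
- **L_SI**, **L_SK** — lacunarity of silhouette and skeleton:
  heterogeneity of the spatial distribution of mass and structure
  (0 for uniform shapes, growing with local contrast).

Together they span a "geometric complexity" space in which taxa of any
body plan can be compared without homologous landmarks.

## Standardization

Input masks are thresholded at mid-intensity (dark-on-light by default),
rescaled so the body length is 860 px, and centered in a 1000x1000 frame.
Body length of an organismal silhouette is the maximum Feret diameter of
the foreground (computed exactly from convex-hull vertices); resampling
is nearest-neighbor so masks stay strictly binary. Reference standards
(squares, disks, iterated fractals) are instead standardized along their
longest axis-aligned extent, because their nominal size is their drawn
extent — Feret scaling would shrink an 860-px square to 608 px via its
diagonal and change what the fixture means.

## Skeletonization

Skeletons are obtained by iterative thinning (Zhang–Suen style, via
scikit-image) without any pruning, so boundary noise survives as short
spurs; a distance-transform medial axis is available as a config switch.
Thinning preserves 8-connectivity and the number of connected
components. A skeleton of at most 4 pixels is "point-like": the shape
(e.g. a filled disk) has no linear structure, the specimen is flagged
*singular*, and its skeleton axes are excluded from space analyses.

## Box counting and lacunarity

For a grid of side `s` anchored at offset `(-dx, -dy)`, `box_count`
records the number of occupied boxes `N`, and the mean `mu` and
population SD `sigma` of foreground pixels per occupied box;
scale-specific lacunarity is `lambda = (sigma/mu)^2` and the overall
lacunarity `L` is the mean of `lambda` across scales. Moments are taken
over occupied boxes only — the convention under which uniformly covered
shapes have `L = 0`. Conservation (`N * mu` = foreground count) holds
exactly and is tested against a brute-force binning oracle.

The box-size ladder is linear, 4–200 px in steps of 4 (0.4–20% of the
1000-px frame). Rotated replicates are computed on an enlarged
(1416-px) canvas so no foreground is clipped, but the ladder stays in
absolute pixels: the standardized body is the same size on every
canvas, and scaling the ladder with the canvas would coarsen the cover
relative to the body and bias slopes low (a config flag restores
proportional scaling).

## The replicated protocol and the covering statistic

Each specimen is analyzed under 10 rotations of 36° x 12 grid offsets
(diagonal offsets at fractions i/12 of the box size; a seeded random
scheme is available), on both the silhouette and the skeleton (the
skeleton is re-thinned after each rotation, since nearest-neighbor
resampling thickens 1-px lines).

The box-counting dimension is defined through the *minimal* covering
count: `D_B = lim ln N(eps) / ln eps` with `N(eps)` the number of boxes
of side `1/eps` *needed* to cover the set. Varying the initial grid
position is what realizes that minimum in practice, so by default the
count entering the regression at each scale is the minimum over the 12
offsets, giving one dimension estimate per rotation; lacunarity, whose
mass moments are position-specific, is estimated per (rotation, offset)
series (120 series). The alternative — a separate regression per
offset, averaged — is available as `count_statistic="per_offset"`, but
every offset then pays the expected "+1 edge box" covering penalty at
every scale, which inflates the dense-shape bias from about −0.1 to
−0.15 and drags a filled square's calibrated dimension to 1.94.
Dimension slopes come from OLS of `ln N` on `ln(1/s)`; a point (N = 1 at
every scale) yields exactly 0.

Reported values are means across estimates, with SDs across estimates;
typical SDs are 0.005–0.04 depending on shape anisotropy.

## Calibration

Finite resolution biases raw estimates of dense shapes low (a filled
860-px square measures ~1.87, deviation ~−0.13). Estimates are passed
through the monotone power law

    D_corr = 0.4565 * D_raw^1.8027 + 0.55436

which rescales the [1, 2] range so that a line measures ~0.98 and a
square ~1.97. `fit_calibration` refits these coefficients from
(raw, theoretical) pairs over the reference suite (R² ≈ 0.996 on the
default suite) and recovers generating coefficients to 1e-4 on
noiseless pairs. Singular specimens keep their raw skeleton dimension
(0 for a point): the calibration is meaningful on the linear-to-planar
range and would otherwise shift an exact 0 to the intercept 0.554.

## Reference standards

The calibration/validation suite contains 12 deterministic forms with
exact self-similarity dimensions: line (1), a graded family of
substitution fractals — quad dust ln5/ln4, Koch curve ln4/ln3, 2-D
Cantor dust ln4/ln3, quad carpet-7 ln7/ln4, Vicsek ln5/ln3, Sierpinski
triangle ln3/ln2, quad carpet-10 ln10/ln4, mixed carpet-7 ln7/ln3,
Sierpinski carpet ln8/ln3 — and disk and filled square (2). Members
were chosen so the estimator's finite-resolution bias is rank-monotone:
distinct dimensions are separated by ≥0.1 (exact ties are handled by
rank correlation), iteration depths give comparable truncation scales,
and solids of extreme aspect ratio are excluded — a filled 1:4 ellipse
(theoretical dimension 2) box-counts at ~1.73 at this resolution,
indistinguishable from a mid-dimension fractal, and would break rank
agreement. Ellipses and further patterns remain available as kinds.
Spearman correlation between raw estimates and theoretical dimensions
over the default suite is 0.996.

## Biomorph generators

**Gielis superformula.** `r(phi) = f(phi) * (|cos(m phi/4)/a|^{n2} +
|sin(m phi/4)/b|^{n3})^{-1/n1}` with ten angular modifiers `f`. Closed
profiles are filled polygons; open curves (e.g. spirals from monotone
`f`) are stroked 1 px wide. The contour-smoothing parameter `p` is
implemented as truncation of the radius profile's Fourier series at
order `p` (one concrete reading of an otherwise informal smoothing
knob).

**Vector biomorphs.** An elliptic body mass (relative size `S_M`,
rotundity `R_M`, orientation `O_M`) plus a primary fan of `N_P` straight
appendages (base length 430 px, thickness `T_P`x860 px) spread
equiangularly over `Ro_P` degrees around a center or periphery anchor,
optionally stretched to the full 860-px length and/or compressed toward
the mass height (implemented as a scale factor on the appendage
component perpendicular to the major axis), with a secondary system
intercalated midway between primary appendages. `N_P = 0` is allowed
(mass-only ellipses); sub-pixel thickness clamps to 1 px.

**Post-transformations.** Central-mass union, skeletonization to
threads, and k-px dilation push shapes into otherwise empty regions.

Sweeps (factorial grids and/or seeded uniform sampling) are reproducible
byte-for-byte given their seed and emit a parameter manifest.

## Ordination, density, disparity

- **Isomap**: symmetric k-NN graph (k = 100, capped at n−1) on Euclidean
  distances of z-scored parameters, Dijkstra geodesics, classical
  (Torgerson) scaling of the geodesic matrix; with k = n−1 it coincides
  with classical scaling of the Euclidean matrix (tested against an
  independent implementation). A disconnected graph is an error naming
  component sizes, with an opt-in to embed the largest component.
  Embedding signs follow a deterministic convention.
- **Density maps**: sums of normalized isotropic Gaussians with scale
  0.15 (embedding units) on a regular grid; additive, non-negative, and
  integrating to the point count.
- **Disparity**: the generalized variance of a group is the determinant
  of its sample covariance (n−1). Group disparity is a bootstrapped,
  rarefied ratio against the group with the highest full-sample
  generalized variance: 1000 replicates each draw 50 rows per group
  without replacement (with-replacement and per-replicate-denominator
  options exist). Ratios are reported on the generalized-standard-
  deviation scale, `sqrt(GV_g / GV_denom)`, which scales as `c^dims`
  under isotropic shrink by `c` and reads as the occupied fraction of
  the field of possibilities; raw determinant ratios would scale as
  `c^{2 dims}`. Disparity uses raw (unstandardized) parameters by
  default.

## Posture robustness

A programmatic articulated humanoid (trunk, head, two arms and legs
with elbow/knee joints) generates posture batteries. Joint ranges
(arms 25–80°, elbows 0–30°, legs 6–26°, knees 0–15° from vertical) keep
limbs from overlapping the trunk or each other; even-index variants are
bilaterally symmetric, odd asymmetric. Across 30–36 seeded postures the
skeleton metrics stay within 2σ ≤ 0.03 while the silhouette dimension
varies more (2σ ≈ 0.03); silhouette *lacunarity* sensitivity, by
contrast, is driven by limb overlap and crossing, which this battery
deliberately excludes, so it is not expected to exceed the skeleton
value here.

## What the synthetic fixtures do and do not show

All tests and the acceptance script run on generated fixtures:
geometric standards with exact dimensions, simulated biomorphs, and the
humanoid battery. These exercise the estimator's operating
characteristics (bias, calibration, rank agreement, robustness,
statistic behaviour) but not the vagaries of real specimen imagery —
manual vectorization noise, texture, partial occlusion — nor the
taxonomic composition of any real sample. Empirical claims about real
organisms' occupation of the space require measured specimen tables.

## Problem sizes and runtime

Full-protocol measurement of a dense 860-px solid takes ~30 s on one
core (120 recorded series x 50 box sizes on ~740k foreground pixels);
thin shapes take ~1 s. The packaged demonstrations are sized
accordingly: the reference-suite validation measures 12 shapes
(~2.5 min), the posture battery 30–36 humanoids (~4 min), and the demo
pipeline (determinism check) measures 200 thin biomorphs under a
reduced protocol (3 rotations x 2 offsets, box step 12) in ~1.5 min per
run — replicate count does not affect the determinism property it
verifies.

## Known limitations

- 2-D silhouettes only; volumetric (3-D) fractal properties are out of
  scope.
- No pruning means skeleton spurs from boundary noise contribute to
  D_SK and L_SK; this matches the measurement convention but makes
  heavy speckle harmful (the loader warns when isolated single-pixel
  islands exceed 5% of the foreground).
- Lacunarity values depend on the standardized resolution and are not
  comparable across different frame sizes.
- The Gielis modifier list is the ten enumerated functions; bilateral
  asymmetries beyond those modifiers are not generated.
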