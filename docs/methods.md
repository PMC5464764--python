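# Methods

This note documents the models, algorithms and design choices behind
`rootshape`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Surface model and conventions

All geometry lives in millimetres in a right-handed frame. Label volumes
are binary voxel arrays indexed (x, y, z); the center of voxel (i, j, k)
sits at `origin + index * spacing`, with no orientation matrix — synthetic
data defines its own anatomical frame (apex at z = 0, crown-to-apex = −z,
mesial = +x, lingual = +y), and real data is expected with user-supplied
apex and mesiodistal direction hints. Surfaces entering the shape pipeline
must be watertight, outward-oriented and genus 0 (V − E + F = 2).

Label resampling is nearest-neighbour (labels stay binary; the pipeline
never resamples intensities). Isosurfaces are extracted by marching cubes
at level 0.5 with optional Taubin smoothing (default 10 iterations), which
is accepted only if it preserves ≥ 99 % of the enclosed volume — the
validation metrics compare volumes, so shrinkage-prone Laplacian smoothing
is deliberately not offered. Rasterization uses scanline parity of voxel
centers, exact for watertight input. Vertex normals are angle-weighted
averages of incident face normals.

## Spherical parameterization and correspondence

Homologous sampling follows the SPHARM point-distribution-model idea: map
each genus-0 surface to the unit sphere, expand the coordinate functions
in spherical harmonics, canonicalize the parameter sphere, and sample at a
fixed set of directions.

* **Poles.** Extremes along the (hinted or first principal) long axis.
  Among vertices within 0.5 mm of the extreme, the laterally most central
  one is chosen: the raw argmax wanders along flat incisal ridges under
  segmentation noise, which destabilized the whole map in testing.
* **Latitude.** The discrete (cotangent) Laplace equation with Dirichlet
  values at the poles, re-graded so that cumulative surface area matches
  spherical-cap area (θ = arccos(1 − 2·A/A_total), interpolated over
  knots uniform in latitude). Pure harmonic latitude with point poles
  degenerates toward the equator; area equalization is what makes the
  sampling density anatomically meaningful.
* **Longitude.** A harmonic cyclic field obtained by cutting the mesh
  along a pole-to-pole path and imposing a 2π jump across the cut. The
  cut is steered along the *facial* meridian: the dilaceration taxonomy
  bends roots mesially, distally or lingually, so the facial azimuth is
  the one least likely to place a bent apex into the cut's discretization
  error. Local relaxation removes any flipped spherical triangle
  (escalating from the 1-ring to the 2-ring and finally releasing the
  poles; failure to untangle is an error).
* **SPHARM fit.** Least squares of real spherical harmonics (default
  degree L = 12, configurable) on each coordinate channel over all mesh
  vertices; the RMS reconstruction residual is reported on the result.
* **Canonicalization.** The parameter sphere is rotated so that the
  degree-1 ellipsoid's longest axis is the pole axis, with the north pole
  mapping toward the apex. The azimuth is anchored to anatomy: on several
  crown-latitude parameter rings, the in-plane second-moment major axis
  (sign-aligned to the mesiodistal hint) defines φ = 0, combined across
  rings by anisotropy-weighted circular averaging. Anchoring to the
  ellipsoid's *second axis* instead — the classical default — proved
  unstable across morphology subgroups: a lingual dilaceration inflates
  the faciolingual degree-1 extent enough to swap axis identity and
  rotate the correspondence by ~90°. Coefficients are re-expanded in the
  rotated frame by dense resampling rather than Wigner rotation.
* **Sampling.** Vertices of the frequency-n geodesic icosahedron
  (10 n² + 2 points; 1002 at the default level 10) in a fixed,
  reproducible order (base vertices, then edge points in sorted edge
  order, then face-interior lattice points). The ordering is part of the
  PDM file contract.

Known limitation: any relative (area-balanced) parameterization
redistributes the sampling when the surface-area composition changes. A
+2 mm root shifts crown labels by roughly 0.3–0.4 mm along the surface,
which is invisible on any one tooth but becomes a systematic group
difference in cohort statistics (see "Statistics" below).

## Rigid alignment

Alignment is strictly rotation + translation: the morphology classes of
interest (long, short) are size differences, so scale is never
normalized. `icp_rigid` is point-to-point ICP over the whole surface with
PCA initialization (all proper axis-sign combinations tried, lowest
starting residual kept, to avoid the 180° flip minimum of elongated
teeth); optional trimming or Cauchy robust weighting is available.
`generalized_procrustes` is classical rigid GPA against the evolving
consensus.

Cohort alignment (`align_cohort`) composes the two: homologous GPA for the
coarse pose (point identity breaks the near-symmetry of incisor
cross-sections, where pure ICP has a degenerate 180° spin), then
closest-point refinement against the pointwise **median** shape with
Cauchy weights (scale 0.5 mm). The median target matters: a mean
consensus averages long and short roots into a shape no subgroup matches,
and every group then absorbs part of the length difference as a pose
shift; typical teeth match the median exactly, and robust weighting lets
genuinely different regions (a bent or elongated apex) disagree without
dragging the pose.

## Averaging, signed distances, classification

The cohort average is the pointwise arithmetic mean of homologous points.
Signed distances use the full 3D offset magnitude, signed by projection
onto the reference's outward normal; the diverging blue–white–red colormap
is clamped at ±1.5 mm (central) / ±3 mm (lateral), raw scalars always
stored alongside colors.

For classification the pipeline compares each tooth against the pointwise
**median** shape by default (`classification_reference` option): the
subgroup criteria are phrased against a "typical" tooth, and the median
remains that standard even when the cohort composition is skewed (in a
cohort that is 40 % long, the mean is not neutral and misreads neutral
teeth as conical).

Regional features are computed on the root (beyond a cemento-enamel
boundary approximated at a fixed 0.40 of the axial extent — a documented
simplification), partitioned into cervical/middle/apical thirds:

* `delta_apex_len` — difference of robust (99th-percentile) axial extents;
  with crown-anchored alignment this reads the apical extension.
* `delta_cervical_width`, `delta_mid_circum` — width and circumference
  changes from the **radius profiles** of the two roots compared at
  matched relative levels of each root's own extent (width change =
  2 × radius change; circumference change = 2π × radius change). The
  profile comparison is intrinsic (alignment-free) and, crucially,
  decoupled from length differences: on a tapered root, comparing widths
  at matched absolute heights misreads a pure length change as a width
  change.
* `apex_deviation` — the lateral offset *at the apex* of the root
  centerline (apical-third slab centroids extrapolated to apex level)
  relative to the upper-root axis, computed per shape and differenced
  against the reference. This is how dilaceration is defined clinically
  (deviation of the apex from the root's long axis); averaging a fixed
  apical cap instead biases the estimate low, and homologous-centroid
  differences additionally conflate residual pose with true deviation.

The decision tree (first match wins): lateral apex deviation > 1 mm →
dilaceration, direction from the dominant lateral component (facial
deviations are folded onto the lingual axis); longer apex (> 1 mm) and
larger circumference (> 0.5 mm) → long; the mirrored conditions → short;
shorter apex with wider cervix → blunt; smaller circumference alone →
conical; otherwise neutral. Thresholds are configuration-exposed and sized
so that the observed inter-rater noise floor (~0.06 mm mean) cannot
trigger a non-neutral call.

## Vertexwise statistics

At each homologous point the two groups' 3D coordinates are compared with
the two-sample Hotelling T², the pooled covariance regularized by λI
(λ = 10⁻⁸·tr S/3) when near-singular. The null distribution is built by
permuting whole-tooth labels (one relabeling applies jointly to all
points, preserving spatial correlation); when the number of distinct
relabelings is ≤ the requested permutation count the full enumeration is
used and flagged exact (p = #{T² ≥ T²obs}/N including the observed
labeling), otherwise Monte Carlo with the add-one convention
p = (1 + #{≥})/(1 + B). The implementation uses the two-group scatter
identity W = T_total − c δδᵀ so each relabeling costs only a group-mean,
with closed-form batched 3×3 inversions. Benjamini–Hochberg step-up at
q = 0.05 over all sampled points (m = 1002) controls the FDR; covariates
are not modelled (the comparisons are two-group subgroup-vs-neutral
maps).

## Synthetic data

`generate_tooth` builds an incisor as superelliptic cross-sections along a
centerline: a crown (exponent blending 2 → 4, bulging to the full
mesiodistal width of 8.8 mm and thinning toward the incisal edge) and a
linearly tapering elliptical root ending in a spherical apex cap, with an
optional centerline bend beyond an onset fraction of the root
(dilaceration) and an axial torsion term. Default dimensions are
textbook-scale for a maxillary central incisor (crown 10 mm, root 13 mm,
cervix 6.5 × 6 mm, apex radius 0.6 mm); the crown width default follows
reported population means. Subgroup presets: long (+2 mm root, +0.3 mm
radial), conical (×0.8 root widths), short (−2 mm, ×0.85), blunt
(−1.5 mm, ×2.5 apex radius, +0.4 mm cervical radial), dilacerations (20°
bend in the named direction). Width effects act on the root profile only,
faded at the CEJ and apex cap — every subgroup definition is a root
criterion, so subgroup crowns remain exchangeable.

Cohorts add two layers of realism around the template:

* **Inter-subject anatomy** (`anatomical_scale`, default 1): per-tooth
  parameter jitter (crown width SD 0.6 mm, matching reported population
  spread; root length SD 1.2 mm; torsion SD 5°; incisal-edge taper and
  bulge variation) plus a smooth per-subject surface relief field
  (0.25 mm SD, few-mm correlation length) standing in for the
  high-dimensional individuality of real crowns. Without this layer the
  within-group covariance is low-rank and the vertexwise T² finds
  near-zero-variance directions in which tiny systematic correspondence
  shifts are "significant" everywhere — a pathology of unrealistically
  clean data, not of real cohorts.
* **Segmentation noise**: per-vertex radial Gaussian noise
  (σ = 0.05 mm default). `perturb_as_second_rater` instead displaces
  along normals with a graph-smoothed (spatially correlated) field —
  repeated human segmentations disagree in patches, not white noise.

What the generator does **not** emulate: real CBCT intensity physics,
enamel/dentin substructure, cingulum and marginal-ridge anatomy, root
cross-sections that deviate from superellipses, and multi-rooted teeth.
Passing tests therefore demonstrate correctness of the measurement chain
and the statistics under controlled conditions, not clinical validity on
patient data.

## Simulation studies and their design

`rootshape.studies` packages the seeded studies used by the acceptance
suite (sizes chosen as the package's own benchmark conditions):

* **Label recovery**: 20 teeth per subgroup, surface noise only
  (`anatomical_scale=0`). Recovery is evaluated on exchangeable cohorts
  because the generator's label is only guaranteed to be the phenotype of
  the template: under anatomical jitter a nominally "long" subject whose
  root jittered 2 mm short genuinely is not long, and counting it as an
  error would measure the labels, not the pipeline.
* **Type-I / FDR calibration**: permutation test on template-plus-noise
  cohorts (10 vs 10, 999 permutations, 500 null replicates pooled over a
  level-4 sampling; 200 replicates with 10 % of points shifted by 3σ for
  the FDR check).
* **Long-vs-neutral replicates** (10 vs 14, 4999 permutations): the
  *power* property (an FDR-significant region on the apical root) is
  asserted on exchangeable cohorts, where the +2 mm effect is a true
  effect for every subject. The *localization* property (≥ 80 % of
  significant points on the root) is measured under realistic anatomical
  variance and is reported rather than guaranteed: the area-redistribution
  artifact described above produces genuine crown-label shifts of
  0.3–0.4 mm for a +2 mm root effect, and with n = 10 vs 14 these remain
  detectable against realistic crown variance in a substantial fraction
  of replicates. Notably, the clinical observation this mirrors also
  reported crown-region significance for most subgroups, so a strictly
  root-exclusive map is not what this method family produces.
* **Dilaceration at small n** (3 vs 14): with realistic variance the FDR
  mask is empty in most replicates — a small bent-apex region cannot
  clear the BH threshold at these group sizes, matching the qualitative
  clinical finding that dilaceration comparisons do not survive FDR.

## Numerical choices and degenerate inputs

Cotangent weights are clamped at 10⁻⁶; flip repair runs up to 2000
passes; ICP converges on an RMS change < 10⁻⁴ mm (100 iterations max,
non-convergence returns the best transform with a warning); GPA converges
when the consensus moves < 10⁻⁶ mm. Region summaries require ≥ 20 points
per named region (an error otherwise, "sampling too coarse"). ICC is the
two-way random-effects absolute-agreement single-measure form ICC(2,1)
(ICC(3,1) selectable) and is undefined (error) when subjects and raters
are all constant. STL welding merges bit-identical coordinates only.
Degenerate first-order ellipsoids (two equal axes within 10⁻⁶) fall back
to the anatomical hints with a warning.
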