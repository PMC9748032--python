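# Methods

This note documents the measurement model implemented by `lesionfit3d`, the
numerical choices behind it, what the synthetic generators do and do not
emulate, and the limitations a user should know about.

## Geometry and units

All internal geometry is in millimetres with 0-based voxel indices and a
voxel-centre convention; diameters are reported in cm and volumes in cc only
at the reporting boundary.  A `VoxelGrid` stores in-plane spacings `dx, dy`,
a slice thickness and an inter-slice gap; consecutive slice *centres* are
`thickness + gap` apart (6 mm at the acquisition defaults of 3 mm + 3 mm).
For data whose NIfTI header z-spacing already encodes centre spacing, the
reader can be given an explicit thickness/gap pair to override it; this is
deliberate, because clinical exports rarely preserve gap semantics.

The slice *profile* used by planimetric volume is thickness + gap: each
contoured slice stands in for its full sampling period, which makes
planimetry a Cavalieri estimator (unbiased in expectation over the lesion's
position relative to the slice lattice).

## Shape-based slice interpolation

Stacked per-slice ROIs are resampled to fine slices (default 1 mm) before
fitting.  Each slice's ROI is converted to a 2D signed Euclidean distance
map (negative inside; the image border counts as outside), the maps are
interpolated linearly along z between consecutive slice centres, and the
interpolated field is thresholded at zero.  This morphs one contour smoothly
into the next — the standard shape-based alternative to stair-step nearest-
neighbour stacking, which would bias a surface fit.  Original slice centres
reproduce their ROIs exactly whenever the centre spacing is a multiple of
the target spacing.  Interpolation between an occupied and an empty slice
collapses the contour almost immediately (the empty slice carries a uniform
large positive distance), so isolated slices do not smear.

**End caps.**  Beyond the first/last occupied slice the lesion must be given
through-plane extent (a single-slice lesion would otherwise be flat).  The
end slice's contour is extended outward by up to half the slice-centre
spacing (3 mm at defaults) while eroding inward by 1 mm per mm of distance
(`end_taper = 1.0`), producing a rounded distance-cone cap.  Two
alternatives were characterized against phantom ground truth and rejected:

* extension by half the *thickness* only (1.5 mm) halves the end-slice
  volume contribution relative to planimetry and systematically truncates
  single-slice lesions;
* constant-shape (flat-disc) caps place many surface points simultaneously
  at extreme radius and extreme z, a configuration no ellipsoid surface can
  follow; they inflated sphere diameters by 8–15% and biased cohort-scale
  volumes by > 20%.

With the tapered cap, cohort-mean fitted volumes on the anisotropic
acquisition grid are within a few percent of generator truth.

## Surface sampling

The fit consumes sub-voxel surface samples: marching-cubes vertices of the
interpolated binary volume at level 0.5 (volume zero-padded so border-
touching lesions close).  Fitting boundary *voxel centres* instead was
measured to shrink every radius by about half a voxel — a −16% volume bias
on a 1 mm grid and far worse in 2.6 mm in-plane voxels — because centres of
boundary voxels lie strictly inside the surface.  `boundary_points`
(voxel-centre extraction with 6-connectivity, border treated as outside)
remains available as a primitive.

## Constrained ellipsoid fitting

Each surface point contributes a design row
`(x², y², z², 2yz, 2xz, 2xy, 2x, 2y, 2z, 1)` against coefficient vector
`u = (a, b, c, f, g, h, p, q, r, d)`.  The fit minimises ‖D·u‖² subject to
`u₁ᵀC u₁ = kJ − I² = 1`, where `u₁` is the quadratic block and C is zero
except its leading 6×6 block (diagonal −1 on the squared terms, (k−2)/2 = 1
on the pairwise terms, −k on the cross terms).  The linear block is
eliminated via the Schur complement and the reduced 6×6 generalized
eigenproblem `M v = λ C v` solved directly; after normalising `v` to unit
constraint value the residual equals λ, so the admissible eigenvector
(positive constraint value) with the smallest eigenvalue is the constrained
minimiser.  `k = 4` guarantees the solution is an ellipsoid for shapes with
comparable semi-axes; smaller k is rejected.

Conditioning: points are centred and scaled to unit RMS radius before the
solve and the coefficients mapped back afterwards — raw mm² monomials are
numerically hostile.

**Elongated shapes.**  The +1 normalisation is only reachable when
`kJ − I² > 0`, which for k = 4 requires a major/minor axis ratio below ~2;
beyond that the constrained minimiser is a biased nearby ellipsoid.  When
the input points lie *exactly* on a quadric (the design matrix has a
relative-1e-10 null singular value) the fit therefore returns the
zero-residual quadric directly, after validating that it is a real
ellipsoid.  Voxelized and noisy data never take this branch.  Fit results
are normalised to |kJ − I²| = 1 (+1 whenever the constrained branch ran).

Geometric conversion is standard: centre from `A x₀ = −b`, semi-axes
`√(−d_c/λᵢ)` from the eigenvalues of the quadratic-form matrix, axes sorted
by descending length (ties broken lexicographically on direction, each
eigenvector's dominant component made positive, right-handedness enforced),
mixed eigenvalue signs rejected as hyperboloid/paraboloid.

**Degenerate inputs.**  Fewer than 10 points, coplanar/conic-degenerate
configurations (design rank < 9) and empty masks raise typed errors.  A mask
occupying a single original slice is refused by default — its through-plane
extent would be pure extrapolation from the end-cap rule — but
`allow_single_slice=True` permits it, and the cohort simulator uses this so
that small lesions visible on one slice are measured rather than silently
dropped.

## Measurements

* `ellipsoid_tmd` = 2·max semi-axis (cm): the major axis, any orientation.
* `ellipsoid_volume` = (4π/3)·a·b·c (cc).
* `axial_max_diameter`: on the axial slice with the largest ROI area (ties:
  lowest slice index), the maximum pairwise distance between inside voxel
  centres, computed over the convex hull (O(h²) exact); collinear slices
  fall back to brute force; a single-voxel slice reports 0 with a warning.
  Sub-pixel edge extent is deliberately ignored.
* `planimetric_volume`: Σ slice areas × slice profile.

## PI-RADS v2.1 size rescoring

`apply_size_criterion` upgrades a lesion to score 5 when its TMD is ≥ the
1.5 cm threshold (inclusive).  By default both score-3 and score-4 lesions
are eligible — the operational behaviour observed clinically when 3D
measurements cross the cut-off — while `upgrade_from=(4,)` exposes the
stricter guideline reading in which the criterion formally separates only 4
from 5.  Cohort percentages use caller-supplied per-score denominators and
round half away from zero.

## Agreement statistics

Differences are ellipsoid − manual; SDs are sample (n−1) throughout.
Bland–Altman limits of agreement are bias ± 1.96·SD of differences; paired
t is two-sided with n−1 df (all-zero differences defined as t = 0, p = 1);
Pearson r refuses constant inputs; normality uses the Lilliefors variant of
the one-sample Kolmogorov–Smirnov test (parameters estimated from the
sample; the naive KS with plugged-in parameters is anti-conservative), with
p-values from the Lilliefors table.  The absolute relative percentage
difference uses the ellipsoid mean as denominator — the convention that
reproduces the published per-score integers from the published means — and
is reported rounded half away from zero with full precision retained in
JSON.  Scatter, Bland–Altman and violin figures are optional conveniences
behind `--plots`; numbers are the contract.

## Synthetic phantoms and cohorts

`voxelize_ellipsoid` rasterizes an exact ellipsoid (voxel inside iff its
centre satisfies the unit form ≤ 1) and returns analytic truth (TV =
(4π/3)abc, TMD = 2a).  `perturb_blob` scales the boundary radius by
1 + amplitude·f(direction) with f a seeded low-order angular-harmonic sum
normalised to max |f| = 1; its truth volume is the rasterized voxel count ×
voxel volume.  Both are deterministic under a fixed spec + seed.

`simulate_cohort` emulates the study conditions: per-score true volumes are
lognormal, moment-matched to the published ellipsoid-method per-score
mean ± SD (0.49 ± 0.31, 0.99 ± 0.58, 1.05 ± 0.78 cc); axis ratios are
b/a ~ U(0.55, 0.9) and c/a ~ U(0.35, b/a); the major axis is tilted
uniformly in [0°, 60°] out of the axial plane so in-plane measurement
genuinely misses it in a known fraction of subjects; the grid is DWI-like
(2.6 × 2.6 mm in-plane, 3 mm + 3 mm profile) with random sub-voxel
placement.  Manual columns are *measured* (planimetry, axial Feret) on the
same mask the ellipsoid pipeline sees, so the 2D-vs-3D underestimation
emerges from geometry rather than being injected.  Placement is conditioned
on visibility: a lesion whose z-extent misses every slice centre has its
through-plane position redrawn, because an invisible lesion cannot enter a
measured cohort.

What the generator does **not** emulate: MRI intensities and contrast,
reader variability in contouring, irregular/infiltrative lesion shapes
(unless `perturb_blob` is used), multifocality, and extra-prostatic
extension.  Passing tests therefore demonstrate correctness of the
measurement pipeline on ellipsoid-like lesions under realistic sampling
geometry — not radiologist-level performance on real images.

## Problem sizes and determinism

The test suite fits ~50 exact-point ellipsoids, a handful of voxelized
phantoms per grid geometry, and one simulated cohort of 200 subjects per
score; the whole suite runs in well under a minute on one core.  Round-trip
phantom checks use a canonical configuration — 30° tilt (the median of the
orientation model) and a centre 1.5 mm off the slice lattice — because
recovery at 6 mm through-plane sampling is placement-sensitive: the same
phantom can read several percent high or low depending on where its centre
falls within the slice period.  That sensitivity is a property of the
acquisition geometry, not of the fit, and is visible in the phantom
characterization.

Every stochastic component takes an explicit seed; identical inputs and
seeds produce byte-identical outputs (report writers sort keys and format
floats at 6 significant digits).

## Known limitations

* The k = 4 constrained fit is biased for axis ratios ≳ 2 on noisy data
  (the exact-interpolation branch only rescues noiseless inputs); strongly
  elongated lesions will read slightly small.
* Through-plane undersampling dominates the error budget: with 6 mm slice
  centres a 12 mm lesion is seen by at most two slices, and single-phantom
  errors of ±15% in volume are possible at unlucky placements even though
  cohort means are nearly unbiased.
* The axial Feret diameter ignores sub-pixel edge extent and in-slice
  perpendicular (RECIST-style) diameters are out of scope.
* Rescoring implements only the size criterion; signal-intensity criteria
  (DWI/ADC/T2), DCE and zone-specific logic of PI-RADS v2.1 are out of
  scope.
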