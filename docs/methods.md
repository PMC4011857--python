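# Methods

This note records how `fissint` models the problem, the parameters
that matter, what the synthetic data does and does not emulate, and
the numerical choices behind the implementation.

## The statistic

Fissure integrity is an area ratio: the fraction of the complete
inter-lobar boundary on which a fissure is actually depicted,

    integrity = 100 · A_detected / A_complete   [%],

computed per fissure (right oblique ROF, right horizontal RHF, left
oblique LOF) and aggregated over the entire lung (ELF) as
`Σ A_detected / Σ A_complete` — an area-weighted mean, so the smaller
horizontal fissure contributes less to ELF than the oblique fissures
(roughly half their weight in the phantom geometry). Ratios are
clamped to [0, 100] after estimator noise; raw values go to the debug
log. Integrity levels use six left-open bins with the first closed at
zero; only values strictly above 90% count as a "complete" fissure,
a deliberate allowance for the error of CT in depicting thin sheets.

## Phantom model

The generator builds the minimal geometry that exercises every
pipeline stage with an analytically known answer:

- Two axis-aligned ellipsoidal lungs (RAS axes; +x right, +y anterior,
  +z superior) on a 128³ grid at (0.7, 0.7, 0.625) mm spacing by
  default — clinical in-plane/through-plane anisotropy on a
  scaled-down thorax.
- Fissures are height-field graphs `z = f(x, y)`, rasterized one voxel
  thick. Oblique fissures are planes tilted ~40° from axial
  (0.85 mm/mm, kept below one voxel of rise per voxel step so the
  rasterization stays 26-connected) with a mild quadratic bow;
  the horizontal fissure is a near-axial sheet (4.6° tilt) over the
  anterior-superior right lung, starting 2 mm anterior of its
  intersection with the oblique fissure so the two sheets remain
  separable at detection. The lobe partition (2 left, 3 right lobes)
  follows analytically from the same surfaces.
- Defects: a union of balls with random centers and relative radii,
  grown as a level set of `min_i dist(v, c_i)/r_i` and cut at exactly
  the level that leaves the requested voxel count — the target
  integrity is hit to carving granularity, deterministically per seed.
  By default both defect centers and removed voxels stay ≥3 mm from
  the sheet edge ("interior" defects, the harder detection case); a
  flag allows marginal defects, the clinically typical pattern. When a
  low target is unreachable interior-only, the whole interior is
  removed and a warning logged; the recorded truth is always the
  achieved integrity measured on the masks with the same area
  estimator the pipeline uses.
- Intensities: parenchyma −850 HU, fissure −700 HU, body 0 HU,
  additive Gaussian noise (default 30 HU) applied after rasterization.
- Spirometry: FVC ~ lognormal around 4 L; FEV₁/FVC and FEV₁ %predicted
  drawn uniformly from bands strictly inside each intended GOLD
  category's cut-points, so the staging rule recovers the intended
  category by construction. Integrity targets are drawn independently
  of category (per-fissure normals, default ROF/LOF 82 ± 8, RHF
  62 ± 18, clipped to [0, 100]) — simulated cohorts carry **no**
  association between severity and completeness, matching the null
  hypothesis the cohort statistics are meant to detect.

What the phantom does *not* emulate: airways and vessels (no tubular
false-positive sources), emphysema texture, respiratory motion,
partial-volume graded fissure intensity, accessory fissures, or
anatomically curved lung shapes. Passing the recovery tests therefore
demonstrates correctness of the geometry-processing chain, not
clinical-grade robustness on real CT.

## Detection

Frangi-style sheetness on the scale-normalized Hessian (σ² γ-norm),
computed with physical-unit Gaussian derivatives (per-axis sigmas
handle anisotropic spacing) at scales {0.7, 1.0, 1.4} mm bracketing
the one-voxel sheet thickness; per-voxel maximum over scales.
α = β = 0.5; the Frobenius constant is c = 0.25·max S over the lung —
the quarter (rather than the conventional half) keeps mid-strength
sheet voxels near full response while still suppressing smoothing
tails and noise. Before filtering, out-of-lung intensities are
replaced by the in-lung median: the ~850 HU body/lung step otherwise
dominates the Hessian for ~3σ around the wall and erases the faint
signature of near-wall sheet voxels. Eigenvalues come from a
vectorized closed-form symmetric-3×3 solver evaluated only at lung
voxels (validated against `numpy.linalg.eigvalsh` in the tests).

Extraction thresholds the response (default 0.6), thins to one voxel
along the local normal by non-maximum suppression, and removes
components below 20 mm². The 0.6 default was calibrated on noise-free
phantoms: the 0.5 contour of the response sits about half a voxel
outside the true sheet edge, inflating recovered areas. When the
source volume is available the pipeline also applies an
intensity-evidence gate: the mean intensity along a 5-voxel in-sheet
line (along the axis with the smallest normal component, which stays
on the sheet even for oblique sheets) must exceed 35% of the sheet's
median contrast over a local background sampled ±2–3 voxels along the
normal (in-lung samples only). Voxels failing the gate but with a
contrast-bearing neighbor one voxel along the normal are snapped there
instead of dropped — non-maximum suppression under noise often parks
the peak one voxel off the sheet.

## Anatomical labeling

Left-lung components are LOF unconditionally. Right-lung components
are RHF when the mean surface normal (principal eigenvector of the
averaged orientation tensor) lies within 35° of the cranio-caudal axis
*and* the centroid falls in the anterior-superior quadrant of the
lung's own bounding geometry (translation-invariant); otherwise ROF.
Components mixing both orientations — the oblique and horizontal
sheets merge near their junction — are split voxel-wise: a quadratic
height field is fit to each orientation cluster (with robust
reweighting) and every voxel joins the surface with the smaller
residual, ties going to the oblique sheet. The cone angle is
config-exposed; orientation is assumed RAS-consistent from the image
header, with no orientation inference.

## Completion

A thin-plate spline (scipy `RBFInterpolator`, smoothing 1.0 by
default) fits the patch's height over its PCA plane, using up to 800
evenly strided points with up to three robust refit passes (points
beyond 3 mm of the fit are discarded — a handful of mislabeled voxels
otherwise bend the extrapolation far outside the lung). The surface is
evaluated on a 0.7 mm in-plane grid spanning the lung's full lateral
extent, triangulated, and clipped by keeping triangles whose centroid
lies inside the trilinearly interpolated lung mask (sub-voxel rim
accuracy; an outer margin of dangling triangles is thereby trimmed).
The completed horizontal boundary is additionally clipped 1.5 mm
(normal distance) short of the completed oblique boundary, the
package's definition of where the RML/RUL interface terminates.
A fissure that is entirely undetected is reported as integrity 0; in
phantom mode the denominator falls back to the analytic boundary area
of the phantom geometry, on real data the case is only flagged.

## Surface areas

Voxel sheets: each voxel contributes its transverse cross-section
divided by |cos θ| of the local normal against the sheet's
single-voxel axis (the dominant physical-normal component, ties broken
z → y → x to match the rasterization and thinning conventions).
Normals are estimated by neighborhood PCA (2.1 mm radius), smoothed
sign-freely via Gaussian-filtered orientation tensors (8 mm support,
needed to average over the rasterization staircase of oblique sheets),
and refined by an ordinary-least-squares height refit over a
cylindrical neighborhood — OLS because the "noise" (half-voxel
rounding) acts only along the rasterization axis, making
total-least-squares PCA slopes biased low. Accuracy against closed
forms: exact for axis-aligned planes, ≤1% for 30–45° tilts, ≤1% for a
1 mm sphere rasterized at 0.2 mm (with smoothing disabled — the
smoothing support must stay well below the curvature radius).
Meshes: the sum of triangle areas. The two estimators agree within a
few percent on phantom sheets and are paired consistently: voxel
estimator for detected patches and truth masks, mesh area for
completed boundaries.

## Cohort statistics

GOLD staging is purely spirometric (post-bronchodilator): non-COPD at
FEV₁/FVC ≥ 70%, else stages I–IV at FEV₁ %predicted ≥80 / 50–80 /
30–50 / <30. Group summaries report sample mean and SD (SD for
single-subject groups is configurable, NaN by default). Distribution
tables count subjects per integrity level × group; per-group
percentages divide by the group total and the pooled column by the
cohort size, with rendering as "count/percent" at 0.1 precision.
Pearson and Spearman correlations delegate to scipy (two-sided
p-values via the t-transform with n−2 df; Spearman uses mid-ranks,
required because GOLD categories are heavily tied) and are cross-
checked against brute-force direct-formula/mid-rank oracles to 1e−12.
Significance is read at 0.05 with no multiple-testing correction.

## Problem sizes and determinism

The validation sweeps use 30 phantoms per condition on 128³ grids with
targets drawn from [20, 95] and noise from 10–50 HU (plus a zero-noise
sweep); the null-association check uses 20 replicates of 500-subject
cohorts. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical seeds give voxel-identical
phantoms and bit-identical pipeline output, which is itself
deterministic (no RNG after generation).

## Known limitations

- The detector is tuned for sheet-on-parenchyma contrast; it has never
  seen vessels, airway walls or emphysematous texture, which on real
  CT are the dominant false-positive sources.
- The intensity-evidence gate assumes the fissure occupies a full
  voxel (true for the phantom's rasterization); graded partial-volume
  fissures would need a softer gate.
- Completion extrapolates a height field; fissures that fold over
  (not a graph over any plane) would be mis-modeled.
- The RHF termination rule (1.5 mm short of the oblique boundary) is
  this package's convention; where the published denominator surface
  ends relative to the mediastinum or the oblique fissure is not
  specified by the underlying studies.
- At 50 HU noise the recovered integrity is biased low by a few
  percentage points (threshold misses plus gate losses); the bias at
  ≤30 HU is within ±1.5 points.
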