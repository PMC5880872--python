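# Methods

This note documents the models, numerical choices and limitations behind
`guidefit`. The package simulates a complete laboratory methodology for
measuring how accurately patient-specific surgical guides can be
positioned on the radius, and analyses the result statistically; every
stage that would be physical in the laboratory (printing, manual
placement, CT scanning) is replaced by an explicit, seeded model.

## Synthetic radius phantoms

A phantom is a surface of revolution r(θ, z) about the z axis:

* a shaft of constant radius (default 10 mm) over a total length of
  240 mm — the scale of an adult radius;
* Gaussian widening of the distal end (factor 1.6 over roughly the distal
  15%) and a milder proximal widening standing in for the radial head;
* a styloid-like Gaussian protrusion at θ = 0 (+x) near the distal end,
  whose peak vertex is exported as the `styloid_tip` landmark;
* `n_anchor_bumps` Gaussian surface bumps (default 24, amplitude 1.2 mm,
  ~5 mm footprint) emulating the bony prominences ("surface anchors") that
  give a guide purchase. They are placed densely on the distal third
  (weight 0.50), sparsely mid-shaft (0.15) and moderately proximally
  (0.35), reflecting where real bone offers distinctive shape; the
  mid-shaft of a radius is nearly cylindrical and anchor-poor.

End caps are triangulated from rim vertices only, so the degenerate
configuration (no widening, no styloid, no bumps) is an exact capped
cylinder — the analytic case several tests pin. Meshes are watertight and
bit-reproducible per seed.

The validation experiments and the default pipeline configuration use
reduced phantoms (72 mm long, 8 mm shaft radius) at the full 0.33 mm voxel
size. Registration accuracy is governed by voxel size, noise level,
contour point count and object curvature — not by bone length — so the
shorter bone preserves the measurement physics while keeping volumes near
2M voxels.

## CT simulation

Volumes are isotropic 0.33 mm grids (voxel centers at
`origin + index·spacing`). Rendering rasterizes each closed mesh by
z-slice polygon cross-sections. Two intensity models are available:

* `supersample=1`: binary center-inside test (bone intensity 1000,
  background 0);
* `supersample=2` (default): fractional occupancy from a 2×2×2 sub-voxel
  grid, i.e. a boundary voxel's value is proportional to the plastic
  fraction it contains. This emulates the partial-volume averaging of a
  real scanner; a purely binary rendering imprints globally coherent
  aliasing on flat guide faces that no physical CT exhibits and that would
  otherwise contaminate registration-accuracy measurements (~0.04 mm of
  apparent surface shift at these settings).

The image is then blurred with a normalized Gaussian PSF (σ = 0.33 mm) and
seeded Gaussian noise is added with σ = 10, i.e. 1% of the bone–background
contrast — chosen to reproduce the sub-voxel registration accuracy regime
of scanned homogeneous plastic models with sharp boundaries, without
claiming scanner realism (no beam hardening, no metal artifacts, no soft
tissue). Scenes (bone plus posed guides) take the union occupancy; bone
and guides are the same printed plastic, so contact zones merge without
contrast, exactly as in the physical reference models.

## Guide design

The CAD chain automates the interactive workflow used clinically. The
anatomic frame is computed first: z is the bone solid's smallest principal
inertia axis (uniform density), signed toward the styloid end; x is the
centroid→styloid direction orthogonalized against z; y = z × x points
volar by convention (the phantom has no intrinsic volar/dorsal asymmetry).

A virtual box spans 20% of the bone length along z, centered on the
requested third, with 2 mm lateral margins; its +y face is the projection
face. A 0.5 mm grid on that face is ray-cast along −y; a pixel is set iff
its ray hits the bone inside the box, recording the first (nearest-face)
intersection. The standard design erodes the silhouette with a 2 px disk
and smooths it with a binary opening (same element); the extended design
dilates by 2 px instead, and its added "lateral" pixels project onto the
opposite box face, which sits at the coronal plane splitting the boxed
bone volume 50/50 (found by voxel counting at 0.5 mm pitch with linear
interpolation). Set pixels become footprint vertices (bone hits for
contact pixels, the opposite face for lateral ones), triangulated by grid
connectivity and extruded 20 mm along the face normal into a watertight
solid. The grid spacing and morphology radii are configuration parameters;
they resolve the anchor bumps while keeping meshes small. Undercuts on
strongly curved bone are not handled specially: the extrusion column of a
contact pixel can graze the bone flank near the silhouette edge, which a
physical mold would have trimmed — irrelevant here because scene
composition takes the union and guide contours exclude near-bone points.

## Placement-error model

Manual guide placement is replaced by a stochastic model: per
(location, design) cell, independent zero-mean normal draws per axis for
translation (mm) and rotation (degrees), composed about the guide's own
centroid in the same T(c+Δ)·Rz·Rx·Ry·T(−c) convention used for error
decomposition, so ground truth round-trips exactly through measurement.
Each operator additionally carries a fixed six-parameter offset drawn once
(sd 0.15 mm / 0.15°) — the physical study quantified no inter-operator variability separately,
so this scale is a documented free parameter. Default cell scales (trans /
rot sd per axis):

| location  | extended      | standard      |
|-----------|---------------|---------------|
| distal    | 0.30 / 0.50   | 0.85 / 0.70   |
| proximal  | 0.65 / 1.10   | 1.20 / 1.30   |
| mid-shaft | 1.05 / 1.90   | 1.60 / 1.60   |

These were chosen once to mirror the orderings the physical experiment
reported — distal most accurate, mid-shaft worst, the lateral extension
improving translational accuracy everywhere while degrading rotational
accuracy on the anchor-poor mid-shaft — at effect sizes comparable to the
regression coefficients the physical study reported (≈1.8 mm mid-shaft effect, ≈1.4 mm
standard-design effect on mTRE). The full factorial is 4 operators × 6
geometries × 3 locations × 2 designs = 144 trials, every combination
exactly once; per-trial seeds derive from the global seed by stable
hashing of the trial identity, so results are independent of execution
order.

## Measurement chain

The reference image (bone + guides planned) is segmented by
threshold-connected region growing (thresholds at 50% and 150% of the
contrast) with binary hole filling, followed by up to 10
curvature-regularized refinement iterations: a voxel flips when the
26-neighborhood mean (weight 0.2) overcomes a graded data term measuring
how far its value is outside the threshold band. On clean data the
refinement is provably an exact no-op, which the tests pin. The assembly
surface is extracted by marching cubes at the 0.5 level of the lightly
smoothed mask (σ = 0.7 voxel — removes the staircase area bias of binary
iso-surfaces at negligible shrinkage).

The double contour samples the surface uniformly (seeded, count =
area/step², step 1.0 mm for bone and 0.7 mm for guides to balance group
sizes) and pairs each point p with p ± offset·n at offset = 1 voxel, where
the blurred edge profile gives maximal inner/outer gray contrast. Clipping
produces five groups: bone points ≥3 mm from every guide, split
distal/proximal at the anatomic mid-plane (split is applied after
removal; a guide straddling the mid-plane simply shortens both bone
groups), and per-guide points ≥2 mm from the bone surface (at the contact
the image has no contrast to register against). Point-to-surface distances
are exact (triangle subdivision + KD-tree pruned closest-point queries).

Registration maximizes the Pearson correlation between template grays and
trilinearly sampled pose-image grays over six parameters about the group
centroid. Nelder–Mead starts from identity (scenes share the world frame;
the interactive initialization of the original workflow is unnecessary
here) with 1 mm / 1° initial simplex steps, terminates at simplex diameter
1e−4 or 2000 evaluations, and restarts twice from the best point with a
10× shrunken simplex; points leaving the volume are dropped from the
metric, and an evaluation losing more than half the points scores −1. The
optimization is fully deterministic. The bone registers as one rigid body
(distal + proximal groups merged, mirroring the physical workflow where
both bone ends constrain M_R).

Errors: E = M_R⁻¹·M_G, decomposed about the clipped-guide-group centroid;
angles extracted from the Rz·Rx·Ry factorization (gimbal flagged within
0.1° of ±90°; re-composition is exact to 1e−10). ΔT and the translation
components are exactly invariant under the anatomic-frame change; ΔR is an
Euler-angle norm and is frame-invariant only to second order in the
angles, which at the sub-10° errors occurring here is a ≤1% effect. mTRE
is computed over the same clipped guide group used for registration, so
the measured and true values are directly comparable.

## Validation experiments

* **Repeat-scan** (`experiments.repeat_scan_validation`): one scene
  rendered once, "scanned" 8 times with independent noise; bone and distal
  guide registered to each of the 7 rescans (14 registrations). Because
  the scans share one grid, the recovered parameters isolate the
  noise-driven error of the registration itself; at the default settings
  the mean recovered translation magnitude is ~6e−4 mm and rotation
  ~4e−3°, comfortably sub-voxel.
* **Known-transform recovery** (`experiments.known_transform_recovery`):
  the distal guide rendered noise-free at 50 random displaced poses
  (≤2 mm, ≤2° per axis) and registered back; median translation recovery
  error ~0.015 mm (≪ 0.1 voxel). The residual is dominated by the finite
  contour sampling and interpolation, not the optimizer.
* **Print-agreement round trip** (`experiments.print_agreement`): each
  phantom voxelized, segmented and re-surfaced, then compared to the
  source mesh by nearest-neighbor distances (mean ~0.13 mm, max
  ~0.5 mm at 0.33 mm voxels). This deliberately measures rendering +
  segmentation + extraction fidelity only; the physically measured
  printed-vs-virtual agreement additionally contains printer and scanner
  error and is a different quantity that an in-silico round trip cannot
  reproduce.

## Statistics

Under the normal/identity GLM the maximum-likelihood fit equals ordinary
least squares; both solution paths (statsmodels IRLS and a direct
normal-equations solve) are implemented and asserted equal. Reference
categories: Location = distal, Extension = extended ("extension yes");
Operator and Geometry enter as fixed effects. Wald chi-square per
coefficient is (β/SE)² and per multi-column effect the quadratic form
βᵀV⁻¹β; CIs are β ± 1.96·SE. SPSS (the tool behind the original analysis) does
not document its exact CI variant, so small discrepancies are possible.
Stepwise reduction drops the single largest-p effect ≥ α = 0.05 per step,
with interactions removed before their main effects become eligible; ties
break toward larger df, then alphabetically. Monte-Carlo checks show
nominal behavior at n = 144 with realistic residual sd: 95% CI coverage
within 95 ± 3% and Wald type-I error within 5 ± 2%.

Because the responses (norms of normal draws) are mildly non-normal, a
Shapiro–Wilk report is provided as an advisory preliminary check; the
analysis proceeds regardless, as the original did.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* of the physical
experiment — factorial design, CT geometry, two-intensity plastic scenes,
effect orderings — but not patient anatomy, printer tolerances, glue
fixation, scanner physics or true operator behavior. Passing tests
therefore validate the measurement and analysis machinery (registration
accuracy, metric algebra, statistical calibration) and demonstrate that
injected location/design effects are recovered end to end; they do not
re-establish the clinical effect sizes, which depend on the six private
patient CTs and human operators. The reported clinical-study coefficients
enter only as the scale reference for the generator's defaults.

## Known limitations

* The placement-error model is diagonal-normal per axis; real operator
  errors are correlated with local bone shape (a mold slides along a
  cylinder's axis, it does not translate isotropically). The location
  effect is injected, not emergent from contact mechanics.
* Guide extrusion does not resolve undercuts; extreme bump amplitudes or
  dilation radii can produce molds a printer could not release from the
  bone.
* The level-set-style refinement is a light curvature-regularized cleanup;
  at the default noise (1% contrast) it is nearly inactive, and it has not
  been exercised against heavy noise or intensity inhomogeneity.
* `polygons_closed`-based slicing assumes meshes whose plane sections form
  closed loops; degenerate tangential sections are avoided by the
  half-voxel grid offset rather than handled exactly.
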