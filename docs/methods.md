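# Methods

This note documents the measurement model, the synthetic data used to
verify it, and the numerical and design choices a maintainer should know
about. Everything quantitative stated here is computed by the test suite
or `scripts/acceptance.py`; nothing is quoted from external data.

## Coordinate and side conventions

All world coordinates are LPS millimetres (+x patient-left, +y
posterior, +z superior — DICOM patient space), voxel indices are
0-based, and `world = origin + direction @ (spacing * index)` with an
orthonormal, right-handed direction matrix. NIfTI files (RAS+) are
flipped on load/save; NIfTI is the canonical writable format and DICOM
series are read-only input with the rescale slope/intercept applied.

Every femur is processed in the **left-femur convention**: right femora
are reflected across the patient mid-sagittal plane (x = 0 by default)
before any processing and results carry a `mirrored` flag. Mirroring is
an exact involution: the voxel array is flipped along the grid axis most
aligned with x and the affine is recomposed so the world-space
reflection is bit-exact; value histograms are untouched. For a left
femur the head points medially toward −x and the coronal projection is
integration along +y.

## Calibration

Rod labels are eroded by one voxel before averaging to suppress
partial-volume surface voxels (the minimum surviving rod size defaults
to 50 voxels). Density is regressed on HU (not the reverse) because the
fitted line is applied in that direction voxelwise. Calibrated
densities may be negative in soft tissue and marrow; nothing is clipped
at this stage. Phantom-less operation is an explicit, user-supplied
fixed affine (`source = "fixed"`), and a reloaded phantom fit becomes
`source = "stored"` (asynchronous calibration); there is no silent
fallback to raw HU.

## Pose normalization

Stage 1 applies the *single minimal rotation* (about shaft-axis × ẑ)
mapping the shaft axis onto +z, rather than sequential coronal/sagittal
rotations: the minimal rotation is unique and order-free, and the
conventional abduction/flexion angles are recovered from the original
shaft axis u as `abduction = atan2(uₓ, u_z)`, `flexion = atan2(u_y,
u_z)`. Stage 2 rotates about +z until the neck axis (neck centre → head
centre) has zero anteroposterior component with the head medial (−x).

Reported `axial_rotation` is the **detected malrotation** — minus the
stage-2 correction angle — so a femur with anteversion `a` scanned with
axial rotation `r` reports `a + r` degrees. With exact landmarks the
three angles are recovered to machine precision (the test suite asserts
0.5° over 50 random poses inside the training-augmentation ranges:
±30° about x, ±15° about y and z).

Pivots do not affect the projected areal density (projection is
translation-invariant) but are fixed for reproducibility: stage 1
rotates about the femur-mask centroid, stage 2 about the head centre.
Composites of the two rotations are represented as rotation + residual
translation about the stage-1 pivot.

Resampling uses trilinear interpolation for scalar volumes and
nearest-neighbour for label masks, onto the input grid, with fill
values 0 (density), −1024 (HU) and 0 (labels).

## Projection, ROI and aBMD

The **femoral volume is extracted before rotation**: the calibrated
density is masked to the femur and negative values are clipped to zero
in the original frame, and that masked volume is resampled to neutral
(one composite resampling when landmarks are supplied; two stage-wise
resamplings when a detector must re-run on the stage-1 volume). This
ordering conserves projected bone mass: masking *after* rotation cuts
the interpolation band at the bone surface and was measured to lose
~2.6 % of mass, while the adopted order conserves DRR mass to <0.2 %
(the suite asserts 2 % over ten random poses).

The DRR integrates the masked density along +y with trilinear samples
every 1 mm (midpoint rule), pixel value `Σ samples × step_cm / 1000` in
g/cm² on a 1 mm pixel grid. The proximal ROI takes bone pixels
(DRR > 0) at or above the distal border 20 mm below the projected
lesser-trochanter tip and on the neck side of the chord through the
projected superior/inferior head–neck-junction points; the femoral-head
side is excluded, matching the DXA "total proximal femur" region that
the four junction landmarks exist to delimit. CT-aBMD is the mean over
included pixels (aBMD = BMC / bone area, the DXA definition — the
denominator choice is ours, made once). Classification uses strict
`aBMD < cutoff` (boundary values are non-osteoporotic) with the
published 0.625 g/cm² screening preset, or a user-supplied T-score
criterion; cross-calibration into another densitometer's units is an
optional affine applied last (BMC is rescaled so aBMD = BMC/area keeps
holding), flagged in the result, and identity by default — published
conversion coefficients are not shipped.

### Known bias of the binary bone support

Bone pixels are defined by `DRR value > 0`. Trilinear interpolation
spreads the bone support by roughly one voxel beyond the true
silhouette, so at 0.8 mm voxels and 1 mm pixels the bone *area* is
inflated by ~5 % while the *mass* is conserved — the mean areal density
is therefore biased low by roughly `perimeter × voxel / area` ≈ 5–10 %
relative to the analytic oracle. The bias is nearly constant across
poses and densities: the pose-invariance coefficient of variation stays
under 2 % and the cohort correlation against the oracle exceeds 0.99,
which is what the measurement is used for (DXA agreement is always
re-calibrated through an affine conversion in practice). The pipeline
vs. oracle unit test therefore asserts agreement within 10 %, a bound
derived from that estimate, not from the observed value.

## Synthetic data

The generator emulates the study conditions rather than clinical
anatomy in full:

* **Phantom** — five labeled parallel rods (hydroxyapatite 0, 50, 100,
  150, 200 mg/cm³) in a zero-density slab; the 0 mg/cm³ region is
  modeled as a labeled rod so each listed density contributes a
  calibration sample. Voxel HU follow `hu_slope·ρ + hu_intercept` plus
  Gaussian noise (defaults 0.8, −10, σ = 5 HU — clinical-protocol
  scale).
* **Femur** — a left proximal femur built from analytic solids: head
  sphere (r = 23 mm), neck modeled as two cone frustums flaring 15 %
  from a 13 mm waist at mid-neck toward both ends (real necks taper, and
  the waist makes the "neck centre = minimal cross-section" landmark
  well-posed), shaft cylinder (r = 14 mm), and a lesser-trochanter bump
  whose tip protrudes 24 mm medially; neck-shaft angle 127°, anteversion
  15°. Each solid has a 3 mm cortical shell (800 mg/cm³) around a
  trabecular interior (150 mg/cm³): a point is trabecular if inside any
  eroded core, else cortical if inside any solid. Landmarks are placed
  analytically (the head–neck-junction circle radius solves the fixed
  point d = √(R² − r(d)²) against the tapered neck) and transformed by
  the injected pose. Background is density-0 soft-tissue-equivalent
  material, not air. Default voxels are 0.8 × 0.8 × 1.25 mm, within the
  clinical acquisition range.
* **Cohort** — n femora of shared geometry with trabecular/cortical
  densities drawn from N(150, 50²) / N(800, 120²) mg/cm³ (clipped to
  plausible ranges), each imaged at a uniform random pose inside the
  augmentation ranges; surrogate DXA-BMD is the analytic oracle plus
  optional Gaussian noise.

What the generator does **not** emulate: trabecular texture, beam
hardening, scanner kernels, metal artifacts, cortical thinning
gradients, or anatomical shape variation. Passing tests therefore
demonstrate the correctness of the measurement chain — calibration,
geometry, projection, ROI logic, statistics — not clinical accuracy on
real scans.

### The areal-density oracle

`reference_abmd` integrates the *analytic* solid geometry along
anteroposterior rays in closed form (sphere and cone-frustum ray
intersections, interval unions for the shell/core decomposition) on a
0.2 mm in-plane grid at neutral pose. It shares no voxelization,
resampling or interpolation code with the pipeline; grid convergence
0.2 mm → 0.1 mm changes the value by <0.3 %. The oracle is linear under
joint scaling of both densities but *not* component-wise (zeroing one
material changes the `> 0` support), so the cohort simulator evaluates
it per case.

### The heuristic landmark detector

`detect_synthetic` stands in for the trained landmark network on
synthetic masks only: head centre by trimmed least-squares sphere fit
seeded at the distance-transform maximum (with ball-likeness and
minimum-radius sanity checks); shaft axis by PCA of the distal 40 % of
the mask, refined on pure-shaft voxels ≥50 mm below the neck (the
spherical distal cut otherwise tilts the axis ~2°); neck centre as the
centroid of the minimal cross-section along the neck corridor
(two-pass, corridor radius tied to the estimated neck radius);
lesser-trochanter tip as the maximal medial offset off the shaft axis
after excluding head and the full neck corridor down to its base; shaft
points at 20/50 mm distal to the tip's axial station; junction points
on the head-sphere/neck intersection circle with the in-plane basis
built from the estimated shaft and neck axes (pose-independent by
construction). Median per-landmark 3-D error over random poses is
≈0.1–2.2 mm (the suite asserts ≤3 mm), and errors change by <1 mm under
a 20° pose change. None of this is expected to work on clinical masks —
attach a real detector through the plugin contract instead.

## Problem sizes and determinism

Default test volumes are ~1–1.5 M voxels (0.8 × 0.8 × 1.25 mm femur,
whole-phantom builds in ~0.2 s, femur renders in ~1.5 s); coarse 1.5 mm
grids are used where sub-millimetre accuracy is irrelevant. Cohort and
pose-sweep checks use 10–50 cases. All randomness flows through
`numpy.random.default_rng` seeds carried in the specs; identical seeds
reproduce volumes, tables and landmark draws bit-exactly.

## Limitations

* The ROI's superior/lateral bounds are implicit (all bone pixels above
  the distal cut on the neck side of the junction chord); DXA vendors
  crop differently, so absolute agreement with any particular
  densitometer requires the affine cross-calibration hook.
* The `> 0` bone-support bias described above makes absolute synthetic
  aBMD low by several percent at clinical voxel sizes; comparisons
  should be correlation/agreement based, as they are clinically.
* One femur mask per invocation; bilateral scans must be split upstream.
* The heuristic detector is synthetic-only; no trained models ship with
  the package.
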