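# Methods

## Model and assumptions

`visfat` treats visceral fat measurement as a deterministic
threshold-and-morphology problem on a Hounsfield-unit grid. The core
assumptions are:

* adipose tissue occupies a fixed HU window (−190 to −30 HU, inclusive at
  both ends), and bone (≥ 200), muscle/organ parenchyma (≥ 30) and air
  (< −220) are separable by global thresholds;
* the abdominal wall musculature, skeleton and air-filled organs together
  enclose the visceral compartment tightly enough that a morphological
  closing with a 20-voxel spherical element (≈ 40 mm), with enclosed
  blanks filled between the dilation and the erosion, recovers the
  peritoneal/retroperitoneal cavity. Wall defects wider than twice the
  kernel radius leak by construction (demonstrated in the tests);
* the caudal surface of the lungs is an adequate proxy for the diaphragm
  (superior bound), and the pubic symphysis — the anteriormost bone in a
  5-voxel midsagittal slab — defines the inferior bound.

All processing happens at a half-resolution working grid (1.96 × 1.96 ×
2.5 mm³) produced by 2×2×2 block averaging; averaging (rather than
subsampling) preserves mean HU so the thresholds behave identically on
rescaled and native-resolution-consistent data. Volumes are reported at
the working resolution (9.604 mm³/voxel); nothing is upsampled back.

## Axis and comparison conventions

Arrays are indexed `[x, y, z]`: x toward the patient's left, y anterior, z
inferior (slice 0 is the most superior). All HU comparisons follow the
stated bounds exactly: `>=` for lower bounds, `<` for the air bound, and
an inclusive adipose window (the upper −30 bound is treated as inclusive;
the alternative changes results only by noise-level voxels). Kernel radii
are in voxel-index units, so at the anisotropic working spacing the
"sphere" is ≈ 20 % oblate along z; this is accepted rather than corrected
because every radius in the method is specified in voxels.

## Morphology engine

Structuring elements are integer offset sets {δ : ‖δ‖ ≤ r}. Small radii
run through dense-footprint binary morphology (scipy.ndimage); radii
above 3 voxels use an exact Euclidean-distance-transform formulation
(dilation: EDT of the complement ≤ r; erosion: EDT to background > r,
with a one-voxel virtual background shell outside the volume). Both
routes select offsets by the same squared-distance comparison, and the
test suite asserts voxel-exact agreement with brute-force offset
iteration, including at r = 20.

Border policy: voxels outside the volume are background for erosion,
hole filling and the body-surface distance map. Closing, however, is
computed on a grid padded by the kernel radius, i.e. closing on the
unbounded grid — otherwise the clipped dilation followed by a
border-as-background erosion shaves foreground near the volume border and
closing loses extensivity. The visceral-region delineation pads the same
way. Connectivity is 6 in 3D and 4 in 2D throughout (components and hole
filling); component ordering is by size with ties broken by the first
C-order voxel index, so every run is deterministic.

## Stage-specific choices

* **Muscle depth rule.** "Distance from the body surface ≥ 5 voxels" is
  applied per voxel (shallow voxels are trimmed from otherwise-valid
  components) after the bone-overlap and ≥ 20-voxel component rules. A
  per-component reading would delete the entire abdominal wall, which the
  visceral delineation needs as its main seed.
* **Bone within trunk.** The bone stage's closing can pick up voxels at
  concavities just outside the body; the result is intersected with the
  trunk so the tissue-map invariants (every tissue ⊆ trunk) hold
  unconditionally.
* **Lung-base surface.** Thin-plate-spline RBF interpolation with zero
  smoothing: exact at the sampled columns and reproducing affine surfaces
  to 1e−6. Columns are thinned to every third sample above 2000 samples
  to bound the dense solve. Far from the lung footprint a thin-plate
  spline extrapolates freely, so the fitted surface is clamped into
  [0, inferior_z] when the measurement range is assembled; this enforces
  the range invariant (superior ≤ inferior everywhere) without touching
  the surface anywhere near the lungs.
* **Pubis search.** Restricted to the caudal half of the volume so ribs
  or sternum cannot be the anteriormost bone in whole-body data; ties in
  anterior position resolve to the most cranial slice (the cranial edge
  of the symphysis). A warning (never an error) is emitted if the hit is
  not in the caudal third.
* **Classification.** Per voxel, after restricting fat to the measurement
  range; this guarantees exact conservation (visceral + subcutaneous =
  range-restricted fat) even for fat components straddling the region
  boundary.
* **Empty-window configs.** Threshold sets must satisfy
  trunk < air < fat_low < fat_high < muscle < bone; a reversed (empty)
  adipose window is rejected at construction rather than silently
  producing zero volumes.

## Synthetic phantoms: what they emulate, and what they do not

The generator paints a tapering elliptical torso from concentric layers —
skin (1 voxel, 20 HU), subcutaneous fat ring (−100 HU), abdominal wall
muscle (6 voxels, 50 HU), organ interior (50 HU) — plus two lung
ellipsoids (−800 HU), a vertebral column (400 HU) with enclosed marrow
cavities (20 HU), a pelvic bone ring whose anterior arc stands in for the
pubic symphysis, visceral fat as chains of overlapping spheres (contiguous
mesenteric-like masses), bowel gas pockets (−1000 HU), and a detached
couch bar. Additive Gaussian noise (default σ = 3 HU) leaves ≥ 10 HU
margin to every threshold. Bone is wrapped in a 3-voxel connective-tissue
cushion (0 HU) and the pelvic interior is connective rather than muscle,
because the muscle rule discards any component containing a bone voxel —
on real anatomy, fascia and disc tissue play this separating role.

The four default adiposity levels (thin → obese) scale the torso, the
subcutaneous ring (4 → 10 voxels ≈ 8 → 20 mm) and the visceral blob count
(5 → 60), giving strictly increasing ground-truth visceral volumes at
≤ 96 × 96 × 144 voxels, so the full pipeline runs in seconds per phantom.
The subcutaneous ring starts at 4 voxels because the depth-≥ 5 muscle rule
(≈ 10 mm at working resolution) would otherwise strip the outer abdominal
wall — a genuine property of the method: subjects with under ~10 mm of
superficial cover lose wall muscle to the depth rule.

Phantoms are generated directly at the working resolution (a 2×
supersampled mode exercises the rescaling stage with genuine
partial-volume mixing at compartment boundaries). They do **not** model
native-resolution partial-volume blur, beam hardening, metal or motion
artifacts, organ-level HU heterogeneity, or anatomical variation beyond
the parameters above — so passing the phantom recovery tests shows the
pipeline implements the stated rules faithfully under realistic contrast
and noise, not that it meets clinical accuracy on arbitrary patients.

Recovery error on phantoms is dominated by one mechanism: the 1-voxel
closing of the bone∪muscle∪air exclusion region seals fat voxels in
single-voxel notches of the discretised surfaces of small fat masses.
The loss is proportionally largest for the thin phantom's small visceral
masses, which is why relative error decreases monotonically from the thin
to the obese phantom in the acceptance checks.

## Reference-table statistics

The embedded 24-subject table (12 per sex, three per BMI category under
20 / 20–25 / 25–30 / over 30) stores printed values. Statistics are
computed at full precision and rounded only for display. BMI is
recomputed as weight/height² because the printed BMI column is rounded to
one decimal; the recomputed BMI reproduces the reference substitute-index
correlations exactly, the printed column does not. The visceral-fat-area
column is printed in whole cm², which perturbs its correlations in the
fourth decimal; the acceptance test bounds those entries at |Δr| ≤ 0.0015
instead of printed-precision equality. The error ratio is defined as
|calculated − true| / true × 100; its per-sex medians reproduce the
reference values exactly under this definition, which validates it.

## Problem sizes

Default phantoms are 96 × 96 × 144 voxels (≈ 1.3 M); a full pipeline run
takes ~2–9 s on one CPU core, the acceptance script ~15 s, and the full
test suite under a minute.

## Known limitations

* Muscle-gap false positives: fat-valued voxels in gaps of the abdominal
  wall inside the visceral region are counted as visceral fat; the method
  has no abdominal-cavity model beyond the large-kernel closing.
* Whole-body inputs are assumed supine with the couch below the patient
  and the pubis in the caudal half; heavily cropped scans (no lungs, no
  pelvis) fail with explicit errors rather than guessing a range.
* DICOM reading supports plain axial single-frame series only (no gantry
  tilt, no multi-frame, no non-axial orientations).
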