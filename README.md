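# visfat — automatic visceral fat volume calculation from CT volume data

Visceral fat volume is a key marker in arteriosclerosis and metabolic
research, but it is usually approximated through substitute indices (BMI,
waist circumference, single-slice fat area) because manual slice-by-slice
segmentation of whole CT volumes is prohibitively slow. `visfat`
implements a fully automatic calculation of the *entire* visceral fat
volume from axial CT volume data, for researchers who need to process
accumulated CT archives: given a DICOM series or a NIfTI/MetaImage volume
in Hounsfield units, it reports visceral and subcutaneous adipose volumes
in cm³ together with the masks that produced them.

## Method

The pipeline is threshold-plus-3D-morphology, run at a halved working
resolution (voxels 1.96 × 1.96 × 2.5 mm³):

1. **Rescaling** — 2×2×2 block averaging to the working resolution.
2. **Trunk extraction** — per axial slice, the largest connected region
   with HU ≥ −400 (rejects the scanner couch) plus enclosed sub-threshold
   regions (lungs, bowel gas); stacked and closed with a spherical
   structuring element *B*₁.₅ (radius in voxels).
3. **Tissue segmentation** —
   *bone*: HU ≥ 200 → dilate *B*₁.₅ → largest component → fill enclosed
   blanks (medullary cavities) → erode *B*₁.₅;
   *muscle*: components with HU ≥ 30, no bone voxel, ≥ 20 voxels, at
   depth ≥ 5 voxels from the body surface (per-voxel depth trim);
   *air*: HU < −220;
   *fat*: −190 ≤ HU ≤ −30 outside the *B*₁.₀-closed union of
   bone ∪ muscle ∪ air.
4. **Measurement range** — superior bound: thin-plate-spline RBF surface
   through the caudal planes of the two lungs (the two largest air
   components); inferior bound: the axial plane through the cranial edge
   of the pubic symphysis, found as the anteriormost bone voxel in a
   9.8 mm midsagittal slab (caudal half of the volume).
5. **Visceral region & volumes** — morphological closing of
   bone ∪ muscle ∪ air with *B*₂₀ (blank filling between dilation and
   erosion); fat voxels inside the region are visceral, outside it
   subcutaneous; volume = voxel count × 9.604 mm³.

Because no CT data ships with the package, a seeded phantom generator
builds torso volumes (skin / subcutaneous fat ring / abdominal wall /
organs / lungs / vertebral column with marrow cavities / pelvic ring /
visceral fat masses / bowel gas / scanner couch) with exact ground-truth
masks, and an evaluation module ships the 24-subject reference table of
true vs automatically calculated volumes and reproduces its validation
statistics.

## Worked example

```bash
python examples/run_on_phantom.py
```

```
phantom:                normal (seed 1)
visceral fat (true):        9.06 cm^3
visceral fat (calc):        8.74 cm^3
relative error:             3.50 %
subcutaneous fat (calc): 1035.25 cm^3
measurement range:      z <= 108 (pubic plane), below the fitted lung-base surface
```

The phantom's analytic visceral fat volume is recovered within a few
percent; the shortfall is fat sealed away by the 1-voxel exclusion
closing around small fat structures — the same mechanism that makes
low-adiposity subjects the hardest case. `examples/reference_statistics.py`
prints the validation statistics of the embedded reference table
(female r = 0.9998, male r = 0.9999 between true and calculated volumes;
median error ratios 4.76 % and 3.73 %), and
`examples/make_phantom_files.py` writes a phantom plus ground truth as
NIfTI files.

The same functionality is available from the shell:

```bash
visfat phantom --spec normal --seed 1 --out ph/
visfat segment --input ph/phantom.nii.gz --out seg/ --no-rescale
visfat evaluate
```

`visfat segment` accepts a DICOM series directory or a NIfTI/MetaImage
file and writes `report.json` (volumes, measurement range, per-stage
voxel counts); every HU threshold and kernel radius can be overridden by
a flag.

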