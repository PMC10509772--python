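# hipbmd

Opportunistic osteoporosis screening from hip CT: a library and CLI that
turn a calibrated CT scan of the hip into a DXA-like **areal bone mineral
density of the proximal femur** (CT-aBMD, g/cm²) and an osteoporosis
classification.

Hip CT is acquired routinely for surgical planning, while DXA — the
diagnostic standard for osteoporosis — is widely underused. When a
calibration phantom is scanned with the patient, CT attenuation can be
converted to volumetric bone density, the femur re-oriented to a
standardized position, and the volume projected into the coronal plane to
emulate the areal density DXA reports. `hipbmd` implements that
measurement pipeline for users who already have (or can generate) femur
segmentations and anatomical landmarks:

1. **Phantom calibration** — ordinary least squares of the nominal rod
   densities ρ (mg/cm³ hydroxyapatite) on the per-rod mean attenuation
   (HU): ρ(v) = a·v + b, applied voxelwise.
2. **Pose normalization** — two landmark-driven rotations to the neutral
   position: the minimal rotation taking the shaft axis (through the
   points 2 cm and 5 cm distal to the lesser-trochanter tip) onto the
   superior axis, then an axial rotation (from head and neck centres)
   that removes axial malrotation and femoral anteversion.
3. **Coronal DRR** — ray integration of the masked, clipped density with
   trilinear sampling at a 1 mm step:
   aBMD(x, z) = ∫ ρ(x, y, z) dy, in g/cm².
4. **Proximal ROI and classification** — bone pixels above the distal
   border 2 cm below the lesser-trochanter tip, femoral head excluded by
   the chord through the superior/inferior head–neck-junction landmarks;
   CT-aBMD = BMC / bone area, classified osteoporotic below a
   configurable cutoff (published screening preset: 0.625 g/cm²).

A synthetic-data module generates rod phantoms and parametric proximal
femora with exact ground truth (landmarks, pose, per-voxel composition,
and a closed-form areal-density oracle), so the whole pipeline is
testable without clinical data. Deep-learning segmentation and landmark
models are deliberately out of scope: masks and landmarks are inputs,
and detectors can be attached through the `hipbmd.detectors` entry-point
group.

## Worked example

Generate a synthetic scan, calibrate, and measure:

```sh
hipbmd simulate --preset phantom --seed 3 --out ph
hipbmd calibrate --ct ph/phantom_ct.nii.gz --rod-mask ph/phantom_rods.nii.gz \
                 --out calib.json
# -> calibration: density = 1.24951*HU + 12.5374 (r^2 = 1.000000, 5 rods)

hipbmd simulate --preset femur --seed 5 --out fx
hipbmd measure --ct fx/femur_ct.nii.gz --femur-mask fx/femur_mask.nii.gz \
               --calib calib.json --landmarks fx/landmarks.csv \
               --out result.json --drr drr.png
# -> CT-aBMD = 0.8693 g/cm^2 (non-osteoporotic, area 23.52 cm^2)
```

The phantom was synthesized with HU = 0.8·ρ − 10 plus scanner noise, so
the fitted line recovers the inverse map ρ = 1.25·HU + 12.5 to within
the noise. The femur preset renders a healthy adult femur (trabecular
150, cortical 800 mg/cm³); its measured CT-aBMD of 0.87 g/cm² sits above
the 0.625 g/cm² screening cutoff, hence *non-osteoporotic*. `result.json`
carries the aBMD, bone area, BMC, both rotation matrices, the detected
positioning angles (the example reports 15° of axial rotation — the
femur's anteversion), ROI pixel counts and a provenance block (package
version, config hash, seed). `drr.png` is the 16-bit coronal DRR with
the raw grid in `drr.csv`.

Agreement/ROC evaluation against a reference standard uses
`hipbmd evaluate --pairs measurements.csv --out report.json` (Pearson r,
Bland–Altman limits of agreement, median absolute error, AUC with the
Youden-optimal cutoff, sensitivity/specificity).

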