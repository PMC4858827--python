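# aneumorph

Quantifying how angiographic imaging modality shapes image-based models of
intracranial aneurysms — at desk scale, on synthetic phantoms with known
ground truth.

Patient-specific models of saccular cerebral aneurysms are reconstructed
from three kinds of angiography: 3D rotational angiography (the clinical
reference, finest resolution), CT angiography, and MR angiography (coarsest,
noisiest). The modality changes the reconstructed lumen geometry, and small
geometric changes propagate into the wall-shear-stress statistics computed
on the surface. `aneumorph` implements the full comparison pipeline for
researchers who want to study, teach, or stress-test this propagation
without patient data or a CFD solver:

1. **Phantom generation** — a saccular aneurysm (sphere sac, cylindrical
   neck stalk) on a straight or curved parent vessel, defined implicitly by
   signed distance fields and meshed by marching cubes, so every shape
   parameter has a closed-form ground-truth value.
2. **Modality imaging** — partial-volume rendering of the lumen at
   modality-specific voxel spacing, Gaussian point-spread blur, and noise
   (3DRA-like / CTA-like / MRA-like profiles).
3. **Reconstruction** — threshold segmentation, 26-connected region
   growing, marching-cubes surface extraction, Taubin smoothing, and
   anatomical partition into sac, neck band, parent-vessel ROI
   (1.5 × the proximal neck diameter along the centerline) and extensions.
4. **Morphometrics** — size, aspect ratio (AR), neck area (NA), parent
   vessel diameter (PVD), size ratio (SR), aneurysm angle (AA).
5. **Hemodynamics** — from a time-resolved WSS vector field over one
   cardiac cycle of period `T`:

   - `AWSS = | (1/T) ∫₀ᵀ WSS dt |`
   - `OSI  = ½ (1 − |(1/T) ∫₀ᵀ WSS dt| / ((1/T) ∫₀ᵀ |WSS| dt))` ∈ [0, 0.5]
   - `AWSSG = (1/T) ∫₀ᵀ √(|∇WSSₓ|² + |∇WSS_y|² + |∇WSS_z|²) dt`

   plus the regional statistics AWSS_A, AWSS_P, LWSS_A (< 0.4 Pa area
   fraction at end diastole), MWSS_A and 90th-percentile WSS at peak
   systole, OSI_A, MOSI_A, HOSI_A (> 0.2 area fraction), and AWSSG_A.
   A synthetic pulsatile WSS generator (low AWSS on the dome, high OSI on
   the body, high AWSSG at the neck) stands in for the CFD solve.
6. **Comparison** — rigid ICP alignment + symmetric point-to-surface
   distance between models; per-parameter percent differences
   `Δ% = |test − ref| / ref × 100` against the rotational-angiography
   model; paired two-sided Wilcoxon signed-rank tests (exact null
   distribution up to n = 25, ties mid-ranked); Cohen's kappa with
   poor / moderate / good agreement categories for categorical flow labels.

## Worked example

`examples/01_phantom_ground_truth.py` builds the reference phantom
(sac radius 3 mm, neck radius 1.5 mm, parent radius 2 mm, meshed at
0.2 mm) and measures it:

```
phantom mesh: 27376 faces, watertight=True
 parameter    truth  measured  error %
      size    5.598     5.598     0.00
        AR    1.866     1.869     0.16
        NA    7.069     7.044     0.35
       PVD    4.000     3.995     0.12
        SR    1.400     1.401     0.12
        AA   90.000    90.000     0.00
```

`size` is the dome height above the neck plane, here the closed form
`R + √(R² − r_n²) = 3 + √(9 − 2.25) ≈ 5.598 mm`; all six parameters are
recovered within a fraction of a percent of their analytic values.

`examples/02_modality_imaging.py` then images that phantom with the three
modality profiles and reconstructs a model from each scan:

```
 modality  voxel mm   volume shape  mean dist mm  max dist mm
 DRA_like      0.15  (169, 49, 79)         0.003        0.094
 CTA_like      0.40   (71, 25, 37)         0.029        0.336
 MRA_like      0.50   (59, 23, 32)         0.075        0.510
```

The mean symmetric surface distance to the true lumen grows monotonically
from the rotational-angiography-like profile to the MR-like profile — the
qualitative modality ordering the pipeline is built to study. The remaining
examples cover boundary-condition helpers (peak Reynolds number 612 for a
4 mm inlet under the default waveform), hemodynamic statistics, rigid
alignment, and the full multi-patient cohort study
(`examples/06_cohort_study.py`, which prints the Δ% ± SE tables and the
surface-distance summary).

A thin command-line interface mirrors the library:
`aneumorph phantom|reconstruct|morpho|hemo|surfdist|compare|run --help`.

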