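# Methods

This note documents the models, conventions and numerical choices behind
`aneumorph`, and what its synthetic experiments do and do not show about
real angiographic data.

## Phantom geometry

The phantom lumen is the union of three signed distance fields (SDFs), all
in millimetres:

- **Parent vessel** — a capped tube of radius `parent_radius` and
  centerline length `parent_length`; with `parent_curvature` κ > 0 the
  centerline is a circular arc of radius 1/κ, otherwise a straight line.
- **Sac** — a sphere of radius `R = sac_radius`.
- **Neck stalk** — a capsule of radius `r_n = neck_radius` along the sac
  axis `u`, joining the vessel lumen to the sac.

The **neck plane** passes through an anchor point a clearance
`lift = 0.5 r_n` above the vessel wall, with normal `ẑ` (the wall normal at
the attachment point) regardless of sac tilt. The sphere center sits at
distance `s + b` along `u` from the anchor, where `b = √(R² − r_n²)` and
`s` is the stalk extension above the plane (`s = 0` for an untilted sac;
for tilt θ > 0, `s = max(1.5 r_n tan θ, 1.05 R/cos θ − b)` so the oblique
neck section stays on the stalk and the sphere clears the plane). Between
the plane and the vessel the stalk forms a cylindrical collar — a proper
anatomical neck — and the stalk's rounded cap above the plane is strictly
submerged inside the sphere, so the surface there is exactly the sphere.

This construction was chosen over a bare sphere ∪ tube union for three
reasons:

1. **Exact closed forms.** Above the neck plane the sac is exactly a
   spherical cap: size `= (s + b)cos θ + R`, neck section area
   `= π r_n²` (ellipse `π r_n²/cos α` under an oblique cut at angle α),
   maximum height `H_max = s + b + R`, and PVD `= 2 · parent_radius`.
2. **A well-posed aneurysm angle.** For a spherical sac and a planar neck
   curve, the farthest dome point from the neck centroid always lies along
   the plane normal, so AA would read 90° for any tilt. With the stalk,
   the neck curve is a central section of the stalk cylinder, its centroid
   lies exactly on the sac axis, and AA = 90° − θ exactly.
3. **No grazing contacts.** A sphere resting tangentially on a tube meets
   it in a razor-thin crevice and touches the neck plane tangentially —
   both sub-voxel features that marching cubes and the sectioning
   machinery cannot resolve reliably. The lifted plane and cylindrical
   collar make every surface/plane intersection transversal.

Meshing evaluates the union SDF on a grid of spacing `mesh_edge_length`
and extracts the zero isosurface with marching cubes (at level −10⁻⁶, so
no grid sample sits exactly on the level — lattice-aligned walls otherwise
produce degenerate sheets). The result is watertight and outward-oriented;
at the default 0.2 mm edge, all six morphometrics are recovered within
0.4% of their closed forms and the labeled sac area matches the analytic
spherical-cap area `2πR·size` within 2%.

## Modality imaging model

`voxelize` renders **partial-volume occupancy**: a linear ramp of the SDF
about zero, 1.5 voxels wide — a scanner integrates signal over each voxel,
so the boundary is sampled smoothly and a clean scan reconstructs with
sub-voxel accuracy (this is what makes the "no blur, no noise" consistency
checks meaningful). Intensity is then scaled between background and lumen
values, blurred with a Gaussian point-spread (`psf_sigma`, mm), and
degraded with seeded i.i.d. Gaussian noise (`noise_sigma`, as a fraction of
the lumen–background contrast). The grid is anchored to integer multiples
of the voxel spacing in world coordinates, which makes re-voxelization of
a reconstructed mesh land on the same lattice (pipeline idempotence).

Default profiles (all config-overridable):

| profile  | voxel (mm) | psf σ (mm) | noise |
|----------|-----------|------------|-------|
| DRA_like | 0.15      | 0.10       | 1%    |
| CTA_like | 0.40      | 0.30       | 3%    |
| MRA_like | 0.50      | 0.45       | 5%    |

Only the ordering (rotational angiography best, MR worst) is
physiologically anchored; the specific numbers are plausible free choices.
The model has no contrast-bolus dynamics, no bone or background anatomy,
no modality-specific artifacts (beam hardening, flow voids) — so passing
tests demonstrate correct propagation of resolution/blur/noise effects,
not clinical realism of any one modality.

## Reconstruction

Threshold segmentation (`auto` = midpoint of the two dominant histogram
modes, found on a zero-padded histogram so the pure-background and
pure-lumen bins count as peaks; Otsu fallback), 26-connected region
growing from a seed (or largest component), marching cubes on the masked
intensity volume at the threshold level (sub-voxel accurate, unlike
meshing the binary mask), and Taubin smoothing (λ = `smoothing_sigma`,
ν = λ/(1 − 0.05λ), so the pass-band condition holds and volume shrinkage
stays below 5%; larger shrinkage warns). Marching-cubes speckle components
are discarded (largest component kept) and meshes are rebuilt
outward-oriented.

Partition: faces on the sac side of the neck plane are `aneurysm`; a band
of width `0.1 × D1` hugging the neck curve **on the parent side** is
`neck_band` (the sac-side cap stays intact so its area matches the
spherical cap); parent faces within axial arclength `1.5 × D1` of the neck
footprint along the centerline are `parent_roi`; the rest is `extension`
and excluded from all statistics. `D1` is measured from a parent cross
section just proximal of the neck footprint (offset 15% of the neck
diameter, growing until a clean closed section is found, to avoid the
sac–vessel junction).

## Morphometrics

- **Neck plane**: least-squares plane through the neck curve, normal
  oriented toward the sac. Maximum diameter = largest chord of the
  projected curve; minimum diameter = minimal caliper width (rotating
  calipers on the convex hull); average = arithmetic mean of the two
  (the combination is not standardized; this choice is config-free but
  documented).
- **NA**: minimum area over cutting planes pivoting about the neck
  centroid — normals perturbed up to ±10° on a polar grid, plus small
  parallel offsets toward the parent (up to 10% of the neck diameter) so a
  cut running exactly along the sac–collar crease cannot spoil the
  section. Candidate loops must enclose the centroid and exceed 40% of the
  straight-cut area (guards against degenerate sliver sections). Section
  area is the shoelace area of the planar loop.
- **AR** uses the average diameter of the *minimal-area neck section*
  (mid-collar), which is far more robust to imaging degradation than the
  raw neck-plane cut; `AR × that diameter = size` holds exactly by
  construction.
- **PVD**: cross sections perpendicular to the parent's principal axis at
  D1 (proximal neck) and D2 (1.5 × D1 further upstream, re-centered on the
  D1 section centroid to tolerate curvature), each measured like the neck;
  PVD = (D1 + D2)/2. Averaging D1 and D2 is the documented choice.
- **SR / AA**: `H_max` is the largest Euclidean distance from the neck
  centroid to an aneurysm vertex (not the perpendicular height);
  SR = H_max/PVD. AA is the inclination of the axis (centroid → farthest
  dome vertex) to the neck plane, in (0, 90]: a perpendicular sac reads
  90°. The two-observer manual measurement of the original protocol is
  replaced by this deterministic computation; observer variability is out
  of scope.

## Hemodynamics

Cycle integrals use trapezoidal quadrature over the stored samples; if the
last sample is not at `T`, the first sample is wrapped around (fields are
periodic). OSI is clamped to [0, 0.5] against round-off and defined as 0
where the WSS vanishes identically. The spatial gradient is the exact
per-triangle linear-shape-function gradient, averaged to vertices with
triangle-area weights; degenerate triangles are excluded. AWSSG is the
*time average of the instantaneous* root-sum-square gradient magnitude of
the three Cartesian WSS components — i.e. the quadrature sits outside the
square root, the standard WSS-gradient definition.

Regional statistics are area-weighted with barycentric vertex areas (one
third of incident triangle areas); "portion of wall" statistics are area
fractions, not vertex fractions, so they are robust to non-uniform
meshing. The percentile is area-weighted with linear interpolation between
order statistics (result never exceeds the maximum). MWSS/90WSS are taken
at peak systole (time of maximum inlet flow), LWSS at end diastole (last
sample of the cycle); both are overridable. MOSI and HOSI are evaluated on
the cycle-integrated OSI map — OSI is a whole-cycle quantity, so
evaluating it "at" a time point is not meaningful; this reading is
documented rather than resolved. AWSS_P uses the parent ROI exactly as
partitioned (1.5 × D1).

### Synthetic WSS generator

The generator replaces the Navier–Stokes solve. It produces a tangential
field aligned with the bulk flow direction, scaled by the instantaneous
waveform `q(t)/q̄`, with: a smooth dome attenuation (default 0.15× base
magnitude, ramped with normalized height above the neck plane), a
direction-reversing cosine component on the lower half of the sac
(weight `body_oscillation_fraction`, default 0.8), a magnitude ramp of
slope `neck_gradient_scale` (default 8 Pa/mm) across the neck band, and a
small seeded static direction jitter. The last timestep is set equal to
the first, making the field exactly periodic. By construction the field
shows low AWSS on the dome, high OSI on the body and high AWSSG at the
neck — the canonical saccular-aneurysm pattern — and with zero oscillation
weight and a constant waveform it is unidirectional (OSI ≡ 0). It is a
*pattern generator*, not a flow solution: no impingement jets, no
secondary vortices, no Womersley physics; hemodynamic comparisons across
modalities therefore isolate geometry-induced differences only, which is
also why the study maps one shared per-patient field onto each modality's
mesh by nearest-vertex projection (paralleling the use of identical inlet
conditions across models).

### Boundary-condition helpers

Mean inlet velocity `v(t) = q(t)/(π(d/2)²)`; peak Reynolds number
`Re = ρ v d/μ` with mm→m conversion, blood treated as Newtonian
(ρ = 1056 kg/m³, μ = 0.0035 Pa·s), outflow split MCA:ACA = 0.65:0.35. The
default waveform is a two-harmonic positive pulse (period 0.8 s, 32
intervals, mean 3.8 mL/s, starting at the diastolic minimum) — a
documented stand-in with the right role and Reynolds range (≈612 at a
4 mm inlet, inside 500–750), not a measured ICA waveform.

## Surface distance

The moving mesh is rigidly aligned to the fixed one: initialization by
centroid shift and the four proper-rotation principal-axes alignments
(best kept), refined by ICP with exact point-to-surface correspondences
(Kabsch updates, deterministic, descent-guaranteed). Distances pool both
directions: every vertex plus ≥ 10 area-uniform samples/mm² of each
surface, each projected exactly onto the closest triangle of the other
(KD-tree over triangle centroids for candidates, exact point–triangle
projection; no spatial-index extras required). The report carries mean,
SD and maximum — the maximum is the symmetric Hausdorff distance on the
samples; the mean is the headline scalar. Whether the original
commercial-tool measurement was one-directional or vertex-based is
unknown; the symmetric surface-based choice is documented.

## Statistics

- `Δ% = |test − ref|/ref × 100` per parameter, against the
  rotational-angiography model as reference; a zero reference flags the
  value undefined and excludes it from cohort summaries with a note.
- Cohort tables report mean Δ% ± SE with SE = sample SD/√n.
- The paired Wilcoxon signed-rank test is applied to the *raw paired
  parameter values* (reference vs test model), not to Δ% — Δ% values
  against a common reference have no natural pairing. Zero differences
  are dropped, ties mid-ranked; the null distribution is exact for n ≤ 25
  (dynamic programming over doubled mid-ranks), normal approximation with
  tie correction above; two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).
  The implementation is hand-rolled because the standard library routine
  refuses exact computation under ties; it is cross-checked in the tests
  against brute-force sign enumeration and against scipy on tie-free data.
  Degenerate input (all differences zero) yields p = 1 with a flag rather
  than an error, and small n computes with a flag — the protocol's n ≥ 5
  guidance is advisory.
- Cohen's kappa is unweighted; κ boundaries 0.4/0.75 assign the boundary
  value to the lower category (the original strict inequalities leave it
  undefined). Two identical constant raters define κ = 1.
- No multiple-testing correction is applied, matching the original
  protocol.

## Study orchestration

`run_study` fans a master seed out via `SeedSequence` into per-patient
seeds (phantom sampling, imaging noise, WSS synthesis, distance sampling),
so the whole study is byte-identical under a fixed master seed. Phantom
parameters are drawn uniformly from configured ranges (defaults: parent
radius 1.8–2.2 mm, sac 2.6–3.4 mm, neck 1.2–1.7 mm clamped below 0.95 ×
sac, curvature 0–0.03 /mm, tilt 0–15°). Per-patient failures are
quarantined and reported, not fatal. Every output embeds the
configuration hash; `summarize_cohort` refuses to mix triplets with
different hashes. The default problem sizes — 5 patients, 0.25 mm phantom
meshes, 32 WSS timesteps, 10 samples/mm² for distances — run the full
study in about one minute on a single CPU and were chosen as the smallest
cohort on which the comparison tables are meaningful.

## Known limitations

- No CFD: pressure, velocity fields, streamline-based flow classification
  and any flow-pattern realism are out of scope; categorical flow labels
  can be supplied externally and are only *compared* (kappa).
- Phantoms are single-sac, branch-free idealizations; branch removal,
  bone, and DICOM semantics are not modeled.
- The NA search and neck-curve extraction assume a reasonably circular,
  planar neck; heavily lobulated or fusiform geometries are unsupported.
- Reported study numbers quantify the synthetic conditions above, not any
  patient cohort; only qualitative orderings (e.g. CT-like models closer
  to the reference than MR-like ones; hemodynamic Δ% exceeding
  morphological Δ%) are expected to transfer.
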