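# Methods

This note documents the model behind `clotseg`, the parameter defaults
and their meaning, what the synthetic phantoms do and do not emulate, the
numerical choices, and the known limitations. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model and assumptions

The method measures thrombus length (mm) and volume (mm³) on CT
angiography from three assumptions:

1. **Contrast contrast.** Patent lumen is contrast-enhanced (~150–300 HU)
   while thrombus is markedly darker (< 80 HU), so a lumen segmentation
   driven by an expected-intensity likelihood never leaks into clot.
2. **Approximate mirror symmetry.** The contralateral artery, reflected
   through the mid-sagittal plane, predicts the course and caliber of the
   occluded artery up to a smooth, few-millimetre anatomical asymmetry
   that a free-form deformable registration can absorb.
3. **Radius collapse marks the clot.** Where the occluded-side lumen
   segmentation finds no contrast disc, the estimated radius drops to
   (near) zero; the ratio rule `r_occ < 0.05 · r_contra` therefore
   delimits the occlusion without relying on thrombus intensity itself —
   which is why the method tolerates hyperdense clots, high hematocrit
   and calcifications, and why poor retrograde filling only moves the
   distal reference to the end of the tracked vasculature (flagged as
   such) instead of breaking the measurement.

The pipeline is deterministic given its configuration seed; every stage
failure is a reported status (`failed:<stage>`, `no-occlusion`), never an
exception, so cohort runs account for every case.

## Parameters

All defaults live in `PipelineConfig` and are individually overridable;
the segmentation operating point is:

| parameter | default | meaning |
|---|---|---|
| vesselness σ_low, σ_up | 1.0, 3.5 mm | scale range of the tubularity filter (vessel radii ~1–4 mm) |
| vesselness α, β, n_scales | 0.5, 0.5, 5 | Frangi sensitivity constants and log-uniform scale count; the structureness scale c defaults to half the maximum Hessian norm per scale |
| contour σ_inside, σ_outside | 20, 20 HU | intensity-likelihood kernel widths inside/outside the lumen |
| contour fraction_outside, p_outside | 0.75, 0.5 | fraction of the ray beyond a candidate boundary tested against the background model; likelihood level below which an outside sample counts as ambiguous and is penalized |
| contour blur σ_distance | 2 mm | circular Gaussian regularization of radius-vs-angle along the boundary |
| radius smoothing | 2 iterations, σ = 0.5 mm | robust weighted Gaussian along arc length |
| B-spline registration | 2 mm grid, 32 bins | control-point spacing and mutual-information histogram bins |
| morphology | opening n=1, dilation n=1 | cubic structuring elements of side 2n+1 voxels |
| occlusion ratio | 0.05 | radius-collapse threshold |
| grow seed offset | 0.5 mm | growing seed distal of the proximal occlusion end (recovery scan to 2 mm, logged when used) |
| section spacing / patch resolution | 0.5 / 0.25 mm | cross-section sampling (sub-voxel at typical 0.5 mm CTA spacing) |

## Stage notes and numerical choices

**Vesselness.** Spacing-aware Gaussian scale space (per-axis σ in voxels
= σ_mm / spacing), γ = 2 normalization, bright-tube condition λ2, λ3 < 0.
The image is mean-centered before filtering: the discrete
second-derivative kernel's weights do not sum exactly to zero, and the DC
level would otherwise leak a spurious Hessian into flat regions; a
relative floor on the structureness scale makes a constant image return
an exactly zero response.

**Tracking.** Dijkstra-type minimal cost path
(`skimage.graph.MCP_Geometric`) on the full 26-connected grid with edge
weight = mean endpoint cost × Euclidean step (mm), i.e. a discrete line
integral of the cost. Tracking operates on a subvolume cropped around the
seed pair (10 mm margin) purely for speed. The raw voxel path is
resampled at 0.5 mm and lightly moving-average smoothed so cross-section
tangents vary smoothly.

**Lumen contours.** Per angle (K = 32 rays, 0.25 mm radial steps), the
boundary maximizes mean-inside-likelihood + mean-outside-score, where the
outside window covers `fraction_outside` of the remaining ray and
ambiguous outside samples (likelihood < `p_outside`) contribute a
penalty. The sample at the candidate boundary itself belongs to neither
side and is excluded from the outside window — including it biases the
boundary one sample outward. The expected inside level is the median HU
along the tracked path (self-calibrating per scan); the background level
is the median of the patch border ring. A ray is unreliable when its best
boundary keeps mean inside likelihood below 0.5; a contour with half its
rays unreliable is unreliable as a whole (on the occluded side that is
the expected signature of thrombus and yields radius 0). Centroids are
polygon (shoelace) centroids of the regularized contour. One refinement
pass (contours → center-of-mass centerline → contours) is applied.

**Radius smoothing.** Weighted Gaussian along arc length whose weights
down-weight (×0.01) samples deviating more than 2 robust SD
(1.4826·MAD, floored at 0.1 mm) from the local window median. Isolated
blooming spikes are pulled to the local level while genuine steps —
lumen→thrombus — are preserved, because on either side of a step the
median votes with the majority.

**Registration.** The image reflected through the symmetry plane (which
shows the contralateral artery at the mirrored position) is the fixed
ROI; registering it to the original image and transforming the mirrored
centerline transports it onto the occluded artery. Mattes mutual
information, random 10% sampling (seeded), LBFGSB, 15 iterations, metric
grid resampled at ≥1 mm for speed. Failure (non-finite metric or
optimizer error) falls back to the unrefined mirrored centerline with a
flag.

**Occlusion extent.** Both radius profiles are resampled to 0.5 mm arc
steps from their proximal ends and compared positionwise on the smoothed
profiles. First/last sub-threshold positions delimit the extent; a run
reaching the profile end sets `distal_is_vasculature_end`.

**Thresholds.** Intensities are sampled by trilinear interpolation at
centerline points. The occluded-side statistics are taken two profile
steps inside the detected extent (falling back to one step, then the open
and closed interval when the clot is very short): the extent endpoints
are localized only to one sample and interface sections blend thrombus
with lumen, which would otherwise inflate the SD and push t_min above a
homogeneous clot's intensity. Region growing compares HU with a ±1e-6
tolerance so exactly-threshold voxels (noise-free phantoms) are kept.

**Tubular mask.** Voxels are assigned by projection onto the occluded
centerline and kept only when the nearest point's arc length lies inside
the extent, so the tube is cut flat at the occlusion ends rather than
growing spherical caps; the one-voxel dilation (compensating
wall-adjacent partial volume) is likewise clipped longitudinally, since
the mask by definition ranges from the proximal to the distal occlusion
location. Length measurement projects every mask voxel to its nearest
centerline point, so curved thrombi measure arc length.

## The phantoms: what they emulate, what they do not

`clotseg.phantom` renders symmetric bifurcating tube trees (default
M1-like: 3 mm-radius, 40 mm trunk, one bifurcation) into HU volumes:
lumen 250, thrombus 45, background 40, optional iid Gaussian noise,
optional σ = 0.5-voxel blur imitating the scanner point-spread function,
spherical calcifications overwriting lumen, and a smooth pseudo-random
displacement of the occluded side only, normalized so its maximum equals
`asymmetry_warp_mm`. Tubes are rasterized by voxel-center distance to the
polyline (sampled at ≤ 0.25 · min spacing), which matches the
voxel-counting volume convention; ground truth (masks, centerlines,
length, volume, seeds, plane) is exact by construction.

Phantoms do **not** emulate: skull/bone, beam hardening, vendor
reconstruction kernels, intensity inhomogeneity within thrombus or lumen,
bilateral disease, or anatomically realistic vascular trees. Passing the
phantom studies therefore demonstrates the geometric and statistical
machinery — tracking, contouring, mirroring, registration, detection,
growing, measurement — under controlled conditions, not clinical-grade
accuracy.

One interaction deserves emphasis. The lower growing threshold
t_min = min + SD, applied to a *homogeneous* intensity distribution, cuts
a fixed bottom quantile of it regardless of the noise level (the minimum
of n samples sits ~1.7–2.4 SD below the mean, so min + SD lands
~0.7–1.4 SD below it). Under iid synthetic voxel noise this makes the
grown mask porous, and the 3³ opening can annihilate it (reported
honestly as `failed:morphology`). Real thrombi are spatially smooth and
heterogeneous and CT noise is correlated by reconstruction, so the
minimum is a genuine dark region and the rule behaves as intended. The
stock agreement cohort (`clotseg.evaluation`) therefore varies geometry
(lengths 2–44 mm, radii 1.3–3.3 mm, straight and curved, asymmetry warp
0–1 mm) on noise-free images, while noise robustness (SD up to 10 HU) is
validated at the occlusion-extent level, where the method is insensitive
to it. Phantom noise levels are free parameters of the generator, not
calibrated to any scanner.

Problem sizes in the stock studies (volumes of roughly 60×130×35 voxels
at 0.5 mm) keep a full pipeline run at a few seconds and the complete
study set within minutes on one CPU.

## Design choices on genuinely open points

- The cross-sectional boundary model is a star-shaped polar optimization
  with circular Gaussian regularization, parameterized exactly by
  σ_inside/σ_outside/fraction_outside/p_outside/blur σ_distance. The
  precise penalty role of `fraction_outside`/`p_outside` is a declared
  interpretation (outside-window width fraction; ambiguity level).
- "32-bit grey level" for the registration metric is read as 32 intensity
  histogram bins — bit depth is meaningless for a similarity metric.
- The symmetry plane is a required input, with an optional estimator that
  registers the volume to its own left-right flip and halves the
  translation; it assumes a near-axis-aligned head and is intended as an
  initializer, not a substitute for an explicit plane.
- The 0.05 radius-ratio rule is applied to smoothed radius profiles;
  radius smoothing is applied to both sides symmetrically.
- The contralateral threshold statistics use the whole tracked
  centerline; the occluded statistics use the extent interior (see
  above).
- ICC defaults to ICC(2,1) (absolute agreement) because method-vs-truth
  offsets must count as disagreement; ICC(3,1) is a switch. Limits of
  agreement use the conventional 1.96 multiplier, not t-based
  small-sample limits.

## Known limitations

- Single seeded path per side: no multi-branch lumen segmentation beyond
  the seeded segment, no bilateral-occlusion handling.
- Oblique (non-axis-aligned) acquisitions must be resampled upstream;
  DICOM series are expected to be converted to NIfTI/MetaImage first.
- The symmetry-plane estimator is translation-only; oblique head tilt
  requires an explicit plane.
- Thrombus density/permeability characterization and branching-thrombus
  subdivision are out of scope.
- Very short clots (~2 mm) leave only a couple of interior sections for
  the threshold statistics; the fallback chain handles them but the
  estimates are correspondingly coarse.
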