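# Methods

This note documents the models, conventions and numerical choices behind
`ctcfi`, and what the synthetic studies do and do not demonstrate.

## Phantoms

`make_colon_phantom` renders an abdominal-CT-like volume: an elliptical
soft-tissue body (semi-axes 45% of the in-plane extent) in exterior air, a
bone-like rod (radius 2.5 mm, posterior, kept well clear of the colon course
so fluid growing cannot reach it), and a tubular air lumen following a
C²-continuous spline through the path control points, resampled at 0.4 voxel
steps. Default Hounsfield classes are air −1000±15, soft tissue 40±20,
tagged fluid 500±30, bone 900±50 — distinct, realistic bands.

Voxels on class boundaries get partial-volume HU from 2×2×2 sub-voxel
occupancy sampling, so walls have a finite-width transition rather than a
1-voxel step. The ground-truth lumen is the set of *majority-air* voxels
(occupancy strictly above ½). The strict inequality matters: occupancy is
quantised to eighths, exact-half voxels are common on the wall, and an
inclusive convention would sweep a whole shell of 50/50 mixture voxels
(HU ≈ −480) into the "air" truth that no intensity model can attribute to
either class.

Sessile polyps are spheres centered on the wall; pedunculated polyps are a
sphere head on a stalk (stalk radius 0.4·head radius, length one head
radius). These shapes are a modeling convention — clinical polyp morphology
is far more varied. Tube ends are cut flat: voxels within 1.5 radii of a
path end point but axially beyond it are removed. With a strongly tilted end
tangent the tube rim can still reach a grid face; this mimics a scan that
truncates the colon and is handled downstream (colon selection only rejects
components touching the *lateral* faces).

Fluid pools fill the gravitationally lowest part of the lumen cross-section
in designated arc segments, by height: the bottom layer of thickness
2·r·fill_fraction. Gravity defaults to +y (the "down" direction of an axial
slice for a supine patient) and is configurable.

`make_tube_mesh` is the analytic counterpart: a parametric cylinder with
hemispherical bumps, exact to floating point, used wherever a test needs an
oracle independent of voxelisation.

## Low-dose CT simulation

The chain is: dequantise HU (add U[0,1), undoing integer quantisation) →
μ = HU·0.001·(μ_water−μ_air)+μ_water → per-slice parallel-beam projection →
T = e^(−R) → Poisson(n₀T)/n₀ + N(0, σ), clipped at ε = 10⁻⁶ → R = −ln T →
filtered back-projection → HU. Design choices:

- **Normalization.** Attenuation slices are stored normalized to [0, 1] with
  the affine constants recorded, but line integrals are taken over the
  *de-normalized* physical μ (1/mm) in mm, so T is a genuine transmission
  fraction and photon statistics are physically scaled. Projecting the
  normalized values directly would inflate attenuation ~35× and make every
  through-body ray opaque at any realistic photon count; recording the
  constants keeps the final HU mapping exactly invertible.
- **Projection accuracy.** Rays are sampled with cubic-spline interpolation
  at one-pixel steps (convention t = y cosθ − x sinθ); backprojection
  interpolates the filtered projections cubically. A bilinear
  rotation-based projector leaves ~90 HU RMS edge error on a soft
  tissue/air disk; the spline pair brings the full-chain high-dose
  round trip to ~12 HU RMS on a 128² disk at 360 angles.
- **Filter.** The ramp is built from the band-limited spatial kernel (no DC
  bias); the Hann window is stretched by the frequency-scaling factor and
  the response is zeroed above scaling × Nyquist. Defaults: Hann at 0.641.
- **Dose presets.** n₀(kVp) = {120: 10⁵, 80: 3·10⁴, 60: 10⁴, 30: 10³}
  photons/bin, σ = 10⁻³ in transmission units, μ_water per kVp from typical
  effective energies ({120: 0.0161, 80: 0.0184, 60: 0.0206, 30: 0.0376}
  mm⁻¹), μ_air = 0. All overridable. Gaussian noise is added in transmission
  units (the alternative — count units — differs only by the n₀ scale).
- **Geometry.** 2-D parallel beam per axial slice, 180 uniformly spaced
  angles by default. Helical/fan geometry, scatter, beam hardening and
  bowtie filtration are out of scope.
- `enhance` offers classical denoisers (Gaussian, per-slice total
  variation) behind the same interface a learned method would use.

## Segmentation

Air thresholding at −800 HU initializes a two-class Gaussian intensity
model; the MRF energy (Potts pairwise λ·[f_i≠f_j] over the 6-neighborhood,
data term −log N(I; μ_f, σ_f)) is minimized exactly by an s-t minimum cut.
Numerical choices:

- **Max-flow capacities.** Float costs are clamped at 10⁴ (binding only
  where a label is hopeless anyway) and scaled by 2¹⁴ to integers, keeping
  every capacity far inside int32 for scipy's solver. The min cut is read
  from a BFS on the residual graph. Exactness is verified against
  exhaustive enumeration on random 2×2×2 instances.
- **Pooled variance.** Class models are fitted by iterative 3σ clipping
  (the background is a soft-tissue/bone/fluid mixture whose raw σ is
  meaningless) and, by default, share the pooled standard deviation. With
  per-class σ the decision boundary sits where the two Gaussians cross;
  because air is far tighter (σ≈15 HU) than the background (20–180 HU after
  reconstruction blur), that boundary lands at −740…−920 HU, inside the
  partial-volume wall band, and systematically erodes the lumen by up to a
  voxel. The homoscedastic model puts the boundary at the midpoint of the
  class means (≈−480 HU), which is exactly the 50% occupancy surface the
  ground truth uses. `fit_intensity_models(..., pooled_sigma=False)` gives
  the heteroscedastic variant.
- **Fluid growing.** Seeds are >300 HU voxels one gravity-step below colon
  air; growth proceeds through >300 HU voxels by steps that never move
  against gravity. It runs after the graph cut and component selection.
- **Colon selection.** Components ≥100 voxels that do not touch the
  volume's four lateral faces survive; several disconnected segments may
  all be kept. No survivor raises `SegmentationFailure`, which the pipeline
  records as a per-case failure rather than a crash.

## Surface, centerline, curvature

Marching cubes runs on the indicator field smoothed with a 1-voxel Gaussian
(binary iso-surfaces carry ~10% staircase area excess and noisy curvature);
normals are oriented into the lumen by probing the mask. The centerline is
a distance-transform-weighted (1/(d+ε)²) shortest path between end points
found by a double geodesic sweep on a 26-connected, Euclidean-weighted lumen
graph; the far set of each sweep is a rim ring whose centroid sits on the
axis, and the end point snaps to the lumen voxel nearest that centroid. The
path is then resampled, lateral-recentred three times onto perpendicular
slab centroids (search radius 2.2 maximal radii — assumes the tube does not
fold back on itself within about two radii), end-extended straight to the
tube openings, smoothed and resampled at 2 mm. Frames are parallel
transported, so the azimuth coordinate cannot flip along the path.

Mean curvature is estimated per vertex by least-squares quadric fitting
(z = ax²+bxy+cy²+dx+ey over the 2-ring in the normal's tangent frame);
H = −(a+c) with z along the lumen-side normal, making protrusions into the
lumen (polyps, H ≈ +1/r) positive and the wall seen from inside
(H = −1/(2R)) negative. Accuracy on analytic fixtures: sphere ~2%, cylinder
~0.4%, plane exact; errors shrink with mesh resolution.

The curvature colormap is a diverging linear map: R = ½+½·H/range,
B = ½−½·H/range, G = ½, clamped at ±range (default 0.5 mm⁻¹, so a 6 mm
hemispherical polyp at H ≈ 0.33 mm⁻¹ does not saturate). Each channel is
monotone, zero maps to neutral gray, and the map is exactly invertible
inside the clamp (H = (R−B)·range), which the detector uses to decode
curvature from fused images.

## Fly-In filet rendering

A rig of k = 8 cameras sits on a centerline point, principal axes radial in
the transported frame, 45° apart, each owning a 360/k sector plus a 5°
margin. Rendering is one cylindrical unwrap: for every output row (arc
position) rays are cast radially from the centerline at every column
(azimuth) against the ring's triangles (chunked Möller–Trumbore with
per-row arc prefiltering; CPU-only and bit-reproducible). A surface point's
column therefore *is* its geometric azimuth, and curvature is continuous
across sector seams by construction — the rig contributes sector ownership
and the visibility score, not pixel stitching. Default resolution is
1 px/degree × 2 px/mm of arc; full ring-face coverage requires the pixel
pitch to be at most about half the mesh face pitch (the reference studies
use 1 mm axial face steps).

Visibility per pixel: FL_v = 1 − cos α · max(0, cos Φ) · min(1, f/d), with
α the angle between the ray and the owning camera's axis, Φ the angle
between the surface-to-camera direction and the cell normal, f the focal
length (10 mm default) and d the hit distance. The exact functional form is
a documented convention (monotone in each factor); cells with FL_v above
0.95 are flagged.

Ring sweeps default to 20 mm rings at 10 mm steps (50% overlap), so every
face and every polyp appears in at least one frame. Truth boxes enclose the
pixels whose cells lie within 1.3 polyp radii of the polyp center. Boxes —
truth and detections alike — are wrap-aware: a blob straddling the 0°/360°
seam yields one box whose column span wraps modulo the image width, and box
IoU accepts an optional wrap period.

## Detection and evaluation

The baseline detector thresholds decoded curvature at 0.15 mm⁻¹ (between
the wall's negative values and a 5 mm-radius polyp's +0.2 mm⁻¹), groups
pixels into wrap-aware connected regions, keeps regions of equivalent
radius ≥3 px, and scores by mean normalized curvature. It is a classical
stand-in that makes the pipeline exercisable end to end; a learned detector
would consume the same fused frames and COCO-style boxes.

The focal loss FL = −w(1−p_t)^γ log p_t (probabilities clamped at 10⁻⁷) is
provided as a tested component with γ = 2 default. Per-patient evaluation
counts a diseased patient with any detection as one true positive
regardless of how many of their polyps were found; a detection in a healthy
patient counts as a false positive by default (the literal alternative —
counting it as a false negative — is available but leaves specificity
degenerate). Per-polyp recall and precision–recall curves (greedy matching
at IoU ≥ 0.3, trapezoid area over recall) are also provided.

## Reference studies and their limits

`ctcfi.studies` fixes the problem sizes used throughout the tests and the
acceptance script: the dose round trip uses a 128² disk at 360 angles; the
segmentation-vs-dose sweep uses ten straight-tube phantoms (32×64×64 voxels
at 1 mm, lumen radius 10 mm, 180 angles) across the four voltage presets;
the detection study uses twenty 60 mm × 10 mm tube meshes carrying 1–3
non-overlapping polyps of radius 3–5 mm. These sizes keep a full run in
minutes on one CPU while leaving each effect measurable.

What passing these studies shows: the simulation chain is self-consistent
and correctly scaled; the graph cut is a true global optimizer; boundary
placement survives reconstruction blur and dose-dependent noise with the
expected monotone degradation; filet geometry maps surface coordinates to
pixels exactly; curvature separates protrusions from wall on clean meshes.

What they do not show: performance on real colons. The phantoms lack
haustral folds beyond what the spline path induces, stool and tagging
inhomogeneity, collapsed segments, peristalsis artifacts and scanner
physics (scatter, beam hardening); polyp morphology is idealized. Detection
numbers on tube meshes are an artifact-level bar for the pipeline, not a
clinical claim.
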