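# Methods

## Problem and approach

Rupture risk in abdominal aortic aneurysms (AAA) correlates with regions of
low wall shear stress (WSS), but computing time-averaged WSS (TAWSS) with
transient CFD takes on the order of an hour per geometry. This package
implements a surrogate pipeline that predicts TAWSS *maps* directly from
surface geometry: the 3-D surface is transformed into a ring of rendered
2-D views, an image-to-image network regresses stress-colored views from
curvature-colored (or shaded) views of the same camera, and masked metrics
score only the pixels occupied by the vessel. The non-Euclidean
geometry-to-geometry problem becomes an image translation problem, with no
assumption that meshes share a vertex count or correspondence.

## Synthetic cohort and pseudo-CFD oracle

Real cohorts and CFD runs are not reproducible in a test environment, so
the package ships a seeded generator of AAA-like shapes and an analytic
stress oracle.

**Geometry.** A circular cross-section is swept along a gently bent
centerline (rotation-minimizing frames); the radius profile is
`R(s) = base_radius · (1 + bulge_factor · G(s))` with `G` a Gaussian bump
(σ = bulge_width/2) at `bulge_center`. The seed perturbs the bend
direction, an off-axis sac displacement (up to 30% of the sac amplitude),
and a smooth low-order radius noise (1% relative by default). Defaults:
base radius 10 mm (normal abdominal aorta ≈ 2 cm diameter), centerline
120 mm, bulge factor 0.8 — a dilatation of 80%, comfortably past the 50%
threshold that defines an aneurysm. Meshes are watertight (capped ends)
and carry arclength, local radius and axial tangent metadata.

**Stress oracle.** Instantaneous WSS magnitude follows the fully developed
laminar pipe-flow law at fixed flow rate, `τ ∝ Q / r³`:

    τ(s, t) = τ₀ · (base_radius / R(s))³ · w(t) / v_ref

directed along the local axial tangent, with `w(t)` a two-phase pulsatile
waveform (diastolic baseline 0.1 m/s, systolic peak 0.6 m/s at 30% of a
1 s cycle) and `v_ref` the default waveform's time mean — so the
straight-tube TAWSS equals τ₀ (default 1.5 Pa, physiological) and scaling
the waveform scales stress linearly. Optional zero-mean Gaussian noise
(Pa, seeded) is added along the stress direction. The sac, having a large
radius exactly where surface curvature is extreme, receives low stress:
the generator reproduces the qualitative anti-correlation between
curvature and WSS that motivates using curvature as the network input.
A sac of twice the base radius yields a stress ratio of 1/8 at the apex —
used as a closed-form check.

**TAWSS.** Simulations run three 1 s cardiac cycles at dt = 0.01 s (300
vector snapshots); TAWSS is the arithmetic mean (rectangle rule) of the
per-step vector magnitudes over the *third* cycle only (100 steps),
discarding start-up transients. Cycle indexing is 1-based.

**What the generator does not emulate.** Patient anatomy (branching,
tortuosity, intraluminal thrombus), turbulence, pressure effects, and any
secondary-flow structure: the oracle is a smooth radial law plus noise.
Passing tests therefore demonstrate that the pipeline can learn *a* smooth
geometry→stress map end to end — they do not certify accuracy on clinical
CFD data.

## Curvature features

Per-vertex signed mean curvature (1/mm) via the cotangent Laplacian with
barycentric vertex areas: the Laplace–Beltrami operator applied to the
coordinates gives the mean-curvature normal; its component along the
outward vertex normal is H (convex bulges positive). Zero-area triangles
are excluded from the stencil; boundary vertices inherit the nearest
interior value. Values are clipped to the per-mesh [1st, 99th] percentiles
before colormap normalization because discrete estimators spike at sliver
triangles and an unclipped range would crush the color contrast. Verified
against closed forms: H = 1/r on spheres, 0 on planes, 1/(2r) on
cylinders (where the cotangent formula is exact on a regular lattice);
rigid invariance to 1e-6, and H → H/s under uniform scaling by s.

## Multi-view domain transformation

Views are produced by an in-package orthographic z-buffer rasterizer with
barycentric interpolation of per-vertex colors — deterministic by
construction, and the foreground mask is the exact triangle-coverage
silhouette rather than a white-pixel heuristic. The geometry is rotated
counterclockwise in `step_degrees` increments (default 30° → 12 views)
about the chosen axis under a fixed camera perpendicular to that axis;
framing is locked per geometry (bounding sphere about the bounding-box
centroid + 5% margin) so apparent size is angle-independent. Default
capture is 768×768, area-averaged down to 256×256 (tests use 64×64
directly). x- and y-axis rings are flagged augmentation-only and never
enter test sets; a seeded runtime zoom (default factor 0.9–1.1, one factor
shared by the input/target of a pair) completes the augmentation.

Scalar fields travel through images via an invertible codec: a 256-entry
rainbow LUT built as a blue→red hue sweep, whose entries are uniformly
separated in RGB so nearest-color decoding inverts encoding exactly (a
named map like `jet` has nearly duplicate entries at its saturated ends
and cannot be inverted reliably; aesthetics were not the requirement).
Normalization range is the per-geometry field [min, max], recorded in the
view metadata; white is reserved for background. Shaded mode uses a
single headlight with a diffuse term and a roughness/metallic-controlled
specular lobe (both 0.5), clamped below pure white.

## Network

A depth-D encoder–decoder of double-conv blocks (3×3 conv → batchnorm →
ReLU, twice), width `n·2^(d−1)` at level d, extended with three skip
systems: full-scale inter-skips (encoder levels 1..d max-pooled to level-d
size, concatenated, reduced by a 1×1 convolution to the level width),
sigmoid-gated encoder intra-skips (shallower maps pooled by 2^(d−i)), and
sigmoid-gated decoder intra-skips (deeper decoder maps bilinearly
upsampled by 2^(i−d)). Gates are parameter-free sigmoids applied after
scaling. The final 1×1 convolution ends in a sigmoid so outputs are valid
[0,1] images. `vanilla_unet` mode strips the gated paths and reduces the
lateral connection to the same-level encoder copy — the plain-UNet
baseline at equal base width. Defaults: depth 5, base width 32 (8 in
tests); inputs must be divisible by 2^(D−1).

Design points that were genuinely open and the choices made:

* the printed channel rule (`n·2^d`) conflicts with "starting from n
  initial filters"; `n·2^(d−1)` is used so level 1 has n filters;
* inter-skips aggregate encoder levels i ≤ d only (the literal summation
  bound), so the scaling operator only ever pools;
* the level-(d+1) decoder map enters both as the main upsampled path and
  as a gated copy (the literal aggregation bound includes i = d+1);
* gated branches keep their source widths; the 1×1 inter-skip reduction
  outputs the level-d width so decoder blocks stay uniform.

The network runs on an in-package reverse-mode autodiff engine over numpy
(NHWC layout; convolution as k² shifted matmuls; bilinear resize as a pair
of interpolation matrices; batchnorm with running statistics; Adam).
Every operator's gradient is checked against central finite differences in
the test suite. float32 is used for training, float64 in gradient checks.

## Training

Adam (lr 1e-4 default) on the *effective MSE*: the mean over foreground
pixels (and channels) of squared intensity differences — background
contributes nothing, and with an all-true mask the loss reduces to plain
MSE. Splitting precedes image generation; whole families (a base geometry
plus its variants) move together, and all real-flagged geometries go to
test. Early stopping monitors a family-stratified validation hold-out
(default 10% of training families — never the test set), patience 30
epochs of a 300-epoch budget by default, restoring best-validation
weights. Zoom augmentation is training-only. The loop is deterministic
given the seeds: all randomness flows from explicit generators, fanned out
per pipeline stage by hashing the stage name with the global seed.

## Evaluation

All metrics are masked. Intensity-scale EMSE feeds
`EPSNR = 20·log₁₀(MAX_I/√EMSE)` with MAX_I = 1. For the normalized errors
the predicted and target pixels are decoded back to Pa through the codec,
and `NMAE = EMAE/max|S|`, `NMSE = EMSE/max|S|`, `NRMSE = ERMSE/max|S|`
are reported as percentages, with max|S| the geometry's peak ground-truth
TAWSS (the codec range maximum). NMSE divides a squared quantity by the
first power of max|S| — kept as the printed convention of the metric set
this follows, with `nmse_squared_norm=True` for the dimensionally
consistent alternative. Aggregates are unweighted means over test images
(not geometries); both conventions are recorded in the report metadata.
A constant-mean-color predictor provides the floor any trained model must
beat.

## Scaled reference experiment

`experiments.scaled_recovery_experiment` is the package's standard
end-to-end check, sized for a single CPU: 40 geometries (8 families × 5)
at 48×20 mesh resolution, 64×64 views in 90° rings, depth-3 width-8
networks, and a compressed schedule — Adam 1e-3 with batch 4 (so both
architectures get enough optimizer steps to converge inside the 30-epoch
cap), early-stop patience 5 on a family-held-out validation loss. It
reports masked metrics for the gated multi-view model, the equal-width
plain UNet, and the constant baseline. At this scale both networks land
far below the baseline; absolute NMAE values are an order of magnitude
above what full-scale training on a real cohort reports, as expected for
minutes of CPU training on a toy oracle.

## Numerical choices and edge cases

* Vertex welding tolerance 1e-6 mm on STL import (triangle soups).
* Degenerate (zero-area) triangles: warned and excluded from curvature;
  skipped by the rasterizer.
* Codec decoding of out-of-gamut colors: nearest LUT entry (always
  resolves; distance available for diagnostics); background decodes to
  NaN sentinels.
* EPSNR of a perfect prediction: +∞ (propagated, not an error).
* Empty foreground masks raise (N_e = 0 leaves the loss undefined);
  zoom factors that crop the whole geometry away are retried (bounded)
  then rejected.
* Early-stopping counter: an epoch with no improvement decrements
  patience; with a frozen model training stops at epoch patience + 1.

## Known limitations

No reconstruction of 3-D stress fields from predicted views; no OSI/ECAP/
RRT indices; the oracle ignores everything hemodynamic beyond a radial
Poiseuille law; the rasterizer has no anti-aliasing (masks are crisp by
design); training is single-CPU numpy — minutes for toy models, not
suitable for 256×256 depth-5 production training.
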