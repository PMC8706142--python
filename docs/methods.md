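# Methods

`trayintake` implements an automated dietary-assessment pipeline for
hospital meal trays: paired before/after RGB-D images are segmented into
food categories and container types, per-component volumes are estimated by
surface subtraction in the depth map, before/after volumes become consumed
fractions, and fractions are multiplied by the kitchen menu's size-scaled
nutrients to give energy and macronutrient intake.  This note records the
models, the numerical choices, and what the synthetic test bed does and
does not establish.

## Geometry and coordinate conventions

The camera looks straight down at a standardised tray from a fixed mount
(default height 0.47 m).  The camera frame has its origin at the optical
centre with +z pointing at the tray; pixel coordinates are 0-based
(row, col) with pixel centres at integer coordinates.  Depth maps are
16-bit single-channel PNGs; `depth_unit` converts counts to metres (1 mm
per count by default, the depth-camera convention) and a zero count marks a
missing measurement.  Back-projection is the standard pinhole model

    z = d * depth_unit,  x = (c - cx) z / fx,  y = (r - cy) z / fy.

The default synthetic intrinsics (`fx = fy = 580`, 640x480) frame a
~50 x 38 cm tray at 0.47 m.  Synthetic frames store depth in 0.25 mm
counts rather than 1 mm: ideal parametric surfaces are perfectly smooth, so
millimetre rounding would alias flat food tops onto one or two discrete
levels instead of dithering away as it does on naturally rough food; the
finer unit keeps quantisation well below the geometric error budget.

## Menu model

A menu (per date and variant) holds at most one dish per category — soup,
meat/fish, side dish, sauce, vegetables/salad, dessert — with the quantity
and the nutrients (energy kcal; carbohydrate, protein, total fat, fatty
acids in grams) of a *normal* serving.  The four prescribable meal sizes
carry exact rational factors (1, 4/3, 2/3, 1/3) applied at lookup time so
one stored menu serves all sizes and normal-size lookups round-trip
bit-identically.  Whether "fatty acids" denotes saturated fatty acids is
left to the deployment; the code only enforces `fatty_acids <= fat`.
Per-100 g storage is deliberately not supported: the kitchen database is
per-serving.

## Synthetic scene generator

The generator is the stand-in for clinical data and defines the study
conditions of every benchmark.  Containers are the four standardised
vessels with fixed calibratable geometry: round plate (flat slab, r =
105 mm), square bowl (flat slab, 100 mm), soup bowl (spherical-cap cavity,
cavity radius 55 mm, depth 30 mm) and dessert glass (cylindrical bore,
r = 30 mm, depth 50 mm).  Foods are parametric solids with closed-form
volumes: cylinders, boxes, spherical caps (domes) and cone frusta on the
flat containers; in the concave vessels foods are *level fills* — a
spherical cap of the cavity sphere in the bowl, a cylinder of the bore in
the glass — matching the physics of soup and of a poured dessert and
keeping the under-food surface analytic.

Rendering is an exact per-pixel ray cast under the full pinhole model (no
orthographic shortcut): each solid contributes an analytic ray-intersection
depth (quadratics for spheres, cylinders and cones; slab tests for boxes),
the nearest hit wins, and the class label tables are fixed (food head:
background, six categories, plate = 7; plate head: background + four
container types; container pixels not covered by food carry food-head
label 7).  Ground truth (masks, clean depth, analytic volumes) is extracted
*before* sensor corruption: Gaussian depth noise (σ in mm), uniform
dropout, and an elevated dropout probability over liquid surfaces that
emulates the reflective-soup failure mode of real depth cameras without
modelling optics.

Consumption: the after frame rescales each food so its remaining
closed-form volume is `(1 - fraction)` of the original — heights scale
linearly for prisms; cap heights solve the cubic cap-volume equation
(Brent's method); fraction 1 removes the item.  Generated datasets sample
meal sizes from the recorded clinical distribution (51 : 6 : 85 : 24 over
166 meals) and consumed fractions from a mixture with point masses at "ate
everything" (20%) and "ate nothing" (10%).

Flat per-item colours with small Gaussian colour noise are intentionally
simple: segmentation on these scenes tests the training loop, the dual-head
wiring and the metric plumbing, not visual robustness.  No texture, no
specularity, no occlusion by cutlery, no deformed or mixed foods — results
on this bed bound nothing about real meal photographs.

## Volume estimation

Writing (u, v) for tray-plane coordinates, a food's volume is
`∫∫ h(u, v) du dv` where `h` is the vertical height of the food surface
above the reconstructed container surface.  Each depth pixel samples the
visible surface; changing variables from pixel indices to (u, v) gives the
per-pixel lateral footprint

    |J| = (z + a z_a)(z + b z_b) / (fx fy),

with (a, b) the ray slopes and (z_a, z_b) the depth-map derivatives along
them.  On locally level surfaces this reduces to the familiar z²/(fx·fy)
footprint; on steep side walls it compresses the footprint so wall pixels
contribute their true sliver of the lateral domain.  A naive per-ray
column integral instead counts the occluded wedge behind vertical walls
(a relative bias of roughly h/z, about 4–5% for a 2 cm item at 45 cm, and
worse off-axis); the Jacobian form removes this and is accurate to ~1% for
every tested shape anywhere on the tray.  Derivatives are taken on a
lightly smoothed copy of the depth (Gaussian, σ = 1.5 px, confined to the
region) for noise robustness; heights use the raw depth.  Missing-depth
pixels are filled from their nearest valid neighbour within the region
(else excluded and counted); a region over 50% missing is flagged low
confidence.  Negative columns are clamped to zero per pixel *before*
summation and the clamped fraction is reported, so noise cannot hide a
bias by cancellation.

### Container surfaces

- **Flat containers** (round plate, square bowl): robust least-squares
  plane `z = c0 + c1 u + c2 v` on the visible container pixels, two rounds
  of residual trimming at max(2 mm, 3 x 1.4826 x MAD).
- **Soup bowl**: algebraic least-squares sphere fit to the visible cavity
  interior, trimmed the same way.  Interior and rim pixels are separated
  *geometrically* — a lateral annulus around the rim-top centre using the
  registry radii — because a depth-percentile split selects the low-noise
  tail of the rim under sensor noise and biases the rim plane shallow.
  A thin visible annulus (soup nearly to the rim) extrapolates the cavity
  bottom poorly even with small residuals, so the fit is accepted only if
  essentially exact (rms < 0.5 mm) or conditioned on a deep visible span
  (≥ 60% of the nominal cavity depth at rms < 1.5 mm); otherwise the
  nominal cavity sphere is hung from the fitted rim plane (registry
  fallback).
- **Glass**: the bore hides its bottom whenever dessert is present, and no
  fit from visible pixels can recover it, so the bottom plane is the
  fitted rim plane displaced by the registry's calibrated cavity depth.
  When the bottom *is* visible (nearly empty glass) a direct plane fit is
  used, gated on planarity and levelness so bore-wall slivers cannot
  masquerade as a bottom.  The registry is justified by the standardised
  tray: hospital crockery is fixed and calibratable once.

Liquids in concave vessels are integrated as levels rather than footprints:
the near rim occludes a crescent of the liquid surface seen off-axis, which
would bias a footprint integral asymmetrically between the before and
after frames.  The level (median visible surface height) with the fitted
cavity model gives the remaining volume in closed form (cap volume in the
bowl, level x bore area in the glass), and the occluded crescent cancels
exactly.

### Fractions and intake

`fraction = clamp((V_before - V_after) / V_before, 0, 1)`; a category
absent from the after mask is fully consumed (1.0); a category absent from
the before frame is skipped with a warning (food cannot appear mid-meal).
Before/after matching is by class label only — the menu structure
guarantees one dish per category.  Intake per category is
`fraction x size-scaled nutrients`; meal totals sum every category except
sauce, which is recorded but discarded from totals, matching the reference
raters' protocol.  Fractions are continuous; an optional snap to a 10% or
25% grid exists for comparison with raters and is off by default.

## Segmentation at desk scale

Three architectures sit behind one config: a five-stack plain encoder with
a pyramid scene-parsing module (the default test backbone), the same
pyramid module on a residual backbone, and a residual backbone with atrous
spatial pyramid pooling.  All consume a single RGB image (depth is not fed
to the network) and emit an 8-channel food head plus, optionally, a
parallel 5-channel plate head.  Pyramid pooled grids are (1x1, 2x2, 3x4,
6x8) on a 30x40 feature map and scale proportionally at other input sizes.
The loss is unweighted per-pixel cross-entropy summed over the active
heads (the loss function is an assumption — a standard choice, not a
recorded fact of the original protocol), optimised by Adadelta (rho 0.95,
eps 1e-6, lr 1).  No pretrained classification weights are used anywhere;
no augmentation is applied.  Training, initialisation and shuffling are
driven by one seed and are bit-deterministic on CPU.

Because no GPU framework is assumed, the layers (convolution with stride
and dilation, pooling, nearest and bilinear resizing, softmax
cross-entropy) are implemented directly on numpy arrays with hand-written
backward passes; gradients are verified against finite differences in the
test suite.  The decoder is a staged resize-convolution (3x3 refinement at
1/16 and 1/4 resolution, 1x1 classifier at full resolution), which avoids
both checkerboard artefacts and full-resolution 3x3 cost.

Desk-scale study conditions: width 16, 96x128 inputs, 20 training scenes,
30 epochs, batch 2 (the small batch trades batch parallelism for more
optimiser steps at identical cost — 90 Adadelta steps at batch 8 are too
few to converge).  Under these conditions the dual-head encoder-PSPNet
reaches food mean IoU ≈ 0.75–0.78 on held-out scenes in about a minute on
one core.  Thin dark sauce patches are the systematic failure (IoU ≈ 0 when
present) — at 96x128 they span a few pixels.  The cross-style pretraining
comparison holds total epochs fixed (10 pretrain + 20 fine-tune vs 30 from
scratch) over 3 weight seeds and compares medians; "does not degrade" is
operationalised as a median drop of at most 0.02, the seed-to-seed
variation observed at these sizes.

## Segmentation metrics

Per-class IoU and accuracy (intersection over ground-truth size), their
means, and directional overlap indexes: for each non-background category
region S_i of the source mask, the best single-region overlap with the
target's regions is taken; `f_min` is the worst ratio (worst-category
performance), `f_sum` the pixel-weighted aggregate; each index is computed
in both directions and combined by the harmonic mean (`F_min`, `F_sum`,
defined 0 at 0/0).  Regions are whole per-category label sets, not
connected components.  Background is excluded from the directional indexes
and, by default, from the per-class means; the plate class is part of the
food head and is included.  Classes absent from both masks contribute no
term (the report lists them); both choices are switchable flags.  All
metrics are verified exactly against an exhaustive set-arithmetic oracle
on random small masks.

## Method comparison

The reference is the arithmetic mean of the raters' per-component
fractions.  Per-component intake multiplies each category's fraction by
its scaled nutrients; the whole-meal model (standard clinical procedure,
SCP) multiplies its single fraction by the summed meal nutrients — on the
same sauce-free basis, so all methods share a nutrient basis.  Agreement
is reported as MAE with the sample SD of absolute errors, MRE
(aggregate-normalised, `100 Σ|e−r| / Σr`; the per-meal-ratio variant is
behind a flag — aggregate normalisation is robust to near-zero-reference
meals), and Pearson r with two-sided p.  Per-category error is the mean
absolute fraction difference x 100, with a whole-meal fraction compared
against every component.  Significance uses two-sided paired t-tests at
α = 0.05 on per-meal absolute energy errors.  The simulated meal sets give
the structural result — per-component estimation beats a whole-meal
fraction whenever components with different energy densities are eaten
unevenly — and that ordering, not any absolute error value, is what the
harness asserts.

## Known limitations

- The synthetic bed validates geometry and plumbing, not appearance:
  nothing here transfers claims to real photographs of food.
- The under-food surface is a modelling choice (plane / sphere / calibrated
  bore), not a reconstruction of any particular prior system; real
  deformable or piled food violates all of these models.
- The glass bottom is unrecoverable from a single frame when covered; the
  calibrated-depth prior is exact for standardised crockery and wrong
  otherwise.
- Volume noise tails remain: an occasional bad rim fit on the narrow glass
  ring under heavy noise produces a large single-category error (the
  benchmarks' medians are stable; the maxima are not).
- Packaged items, cutlery occlusion and barcode-based products are out of
  scope.
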