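# trayintake

Automated dietary assessment for hospitalised patients from before/after
RGB-D images of standardised meal trays.

Malnutrition monitoring on wards depends on knowing how much of each served
meal a patient actually ate. The usual practice — nursing staff eyeballing
a single whole-meal percentage — is coarse and subjective. `trayintake`
implements the image-based alternative: a fixed overhead RGB-D camera
photographs the tray before and after the meal; the images are segmented
into the six food categories (soup, meat/fish, side dish, sauce,
vegetables/salad, dessert) and four container types; per-component volume
is estimated from the depth map by subtracting the reconstructed container
surface from the food surface; and the consumed fraction of each component
is converted into energy and macronutrient intake through the kitchen's
menu database.

For one component with before/after volumes V_b, V_a and size-scaled
nutrients **n**:

    fraction f = clamp((V_b − V_a) / V_b, 0, 1)
    intake     = f · (size factor) · n,      size factor ∈ {1, 4/3, 2/3, 1/3}

with volume integrated over the component's pixels as
`V = Σ h(u, v) · |J|`, where `h` is the vertical height of the food surface
above the reconstructed plate surface and `|J| = (z + a·z_a)(z + b·z_b)/(fx·fy)`
is the pixel's lateral footprint under the pinhole model. Sauce is recorded
but excluded from meal totals, matching the dietitians' protocol.

The package contains:

- `menu_db` — menu database I/O (CSV) and exact rational meal-size scaling;
- `rgbd_io` — registered RGB + 16-bit depth PNG frames, intrinsics,
  pinhole back-projection to point clouds;
- `synthetic_scene` — an analytic ray-cast generator of overhead tray
  scenes (four standardised containers, parametric foods with closed-form
  volumes, paired before/after frames at specified consumed fractions) —
  the test bed standing in for clinical data;
- `segmentation` — dual-head (food + plate) segmentation networks
  (encoder/residual backbones with pyramid scene parsing, and an atrous
  spatial-pyramid variant) implemented on a small numpy autodiff core,
  trainable on a CPU in minutes at desk scale;
- `seg_metrics` — per-class IoU/accuracy and the directional overlap
  indexes f_min/f_sum with their harmonic means F_min/F_sum;
- `volume_intake` — container-surface reconstruction, volume integration,
  consumed fractions, intake;
- `evaluation` — the method-comparison harness: rater-mean reference,
  whole-meal (standard-clinical-procedure) model, MAE/MRE/Pearson,
  per-category errors, paired t-tests, plots.

## Worked example

Generate a small synthetic dataset and estimate one meal end to end with
ground-truth masks:

```python
import numpy as np
from trayintake import (SYNTHETIC_INTRINSICS, MEAL_SIZES, NutrientVector,
                        SegMaskPair, estimate_meal, make_before_after_pair,
                        random_scene)

rng = np.random.default_rng(7)
spec = random_scene(rng)                       # soup bowl + plate + dessert vessel
fractions = {f.category: 0.6 for f in spec.foods}
before, after, gt = make_before_after_pair(spec, fractions)

masks_b = SegMaskPair(gt.before.food_mask, gt.before.plate_mask)
masks_a = SegMaskPair(gt.after.food_mask, gt.after.plate_mask)
menu = {f.category: NutrientVector(200, 20, 10, 8, 4) for f in spec.foods}

rec = estimate_meal(before, after, masks_b, masks_a, menu,
                    MEAL_SIZES["reduced"], SYNTHETIC_INTRINSICS)
print({c: round(f, 3) for c, f in rec.fractions.items()})
print(round(rec.totals.energy, 1), "kcal")
```

```
{'soup': 0.605, 'meat_fish': 0.6, 'side_dish': 0.599, 'vegetables_salad': 0.591, 'dessert': 0.592}
398.2 kcal
```

Every component's recovered fraction is within a few thousandths of the
true 0.6, and the energy total is `Σ f × (2/3) × 200 kcal` over the five
non-sauce components — 398.2 kcal against the exact 400 kcal, the gap
being the small per-component fraction deviations.

The same pipeline is scriptable from the shell: `trayintake simulate`,
`train-seg`, `predict-seg`, `eval-seg`, `estimate`, `compare` (see
`trayintake --help`).

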