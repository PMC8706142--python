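"""Desk-scale benchmark experiments exercising the whole pipeline.

Each function generates its own synthetic inputs from a seed, runs the
package end to end, and returns summary numbers.  They are the common
engine behind the acceptance checks and the reproduction script; sizes are
chosen so the full set runs in minutes on one CPU core.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .labels import FOOD_LABELS, SegMaskPair
from .menu_db import MEAL_SIZES, NutrientVector
from .rgbd_io import depth_to_cloud
from .synthetic_scene import (
    CONTAINER_GEOMETRY,
    MEAL_SIZE_COUNTS,
    SYNTHETIC_INTRINSICS,
    SceneSpec,
    SolidSpec,
    analytic_volume,
    fill_spec_for_bowl,
    fill_spec_for_glass,
    make_before_after_pair,
    random_scene,
    render_scene,
)
from .volume_intake import (
    estimate_food_volume,
    estimate_meal,
    reconstruct_plate_surface,
)

__all__ = [
    "meal_size_distribution",
    "metric_oracle_check",
    "volumetry_benchmark",
    "fraction_benchmark",
    "segmentation_benchmark",
    "comparison_benchmark",
]


def meal_size_distribution(counts: "dict[str, int] | None" = None) -> dict[str, float]:
    """Percentage share of each meal size in the study population."""
    counts = counts or MEAL_SIZE_COUNTS
    total = sum(counts.values())
    return {label: 100.0 * n / total for label, n in counts.items()}


# --------------------------------------------------------------------------
# 1. metric cross-check against a brute-force implementation


def _brute_force_metrics(gt: np.ndarray, pred: np.ndarray) -> dict:
    """Set-arithmetic reimplementation of IoU/accuracy/f-indexes (per pixel sets)."""
    def coords(m, c):
        return {(i, j) for i in range(m.shape[0]) for j in range(m.shape[1]) if m[i, j] == c}

    out = {"iou": {}, "acc": {}}
    for c in sorted(set(gt.reshape(-1)) | set(pred.reshape(-1))):
        g, p = coords(gt, c), coords(pred, c)
        if g | p:
            out["iou"][c] = len(g & p) / len(g | p)
        if g:
            out["acc"][c] = len(g & p) / len(g)

    def f_dir(src, tgt, mode):
        scs = [c for c in sorted(set(src.reshape(-1))) if c != 0]
        tcs = [c for c in sorted(set(tgt.reshape(-1))) if c != 0]
        ratios, bests, sizes = [], [], []
        for ci in scs:
            s = coords(src, ci)
            best = max((len(s & coords(tgt, cj)) for cj in tcs), default=0)
            ratios.append(best / len(s))
            bests.append(best)
            sizes.append(len(s))
        return min(ratios) if mode == "min" else sum(bests) / sum(sizes)

    out["f_dir"] = f_dir
    return out


def metric_oracle_check(seed: int, n_pairs: int = 100, shape=(8, 8), n_classes: int = 4) -> dict:
    """Compare every metric with the brute-force oracle on random mask pairs."""
    from .seg_metrics import class_accuracy, f_directional, iou

    rng = np.random.default_rng(seed)
    mismatches = 0
    checks = 0
    for _ in range(n_pairs):
        gt = rng.integers(0, n_classes, shape)
        pred = rng.integers(0, n_classes, shape)
        oracle = _brute_force_metrics(gt, pred)
        for c, v in oracle["iou"].items():
            checks += 1
            mismatches += abs(iou(gt, pred, c) - v) > 1e-12
        for c, v in oracle["acc"].items():
            checks += 1
            mismatches += abs(class_accuracy(gt, pred, c) - v) > 1e-12
        if (gt != 0).any() and (pred != 0).any():
            for mode in ("min", "sum"):
                for s, t in ((gt, pred), (pred, gt)):
                    checks += 1
                    mismatches += (
                        abs(f_directional(s, t, mode) - oracle["f_dir"](s, t, mode)) > 1e-12
                    )
    return {"n_pairs": n_pairs, "n_checks": checks, "n_mismatches": int(mismatches)}


# --------------------------------------------------------------------------
# 2. volumetry accuracy on known solids


def _volumetry_cases():
    geo = CONTAINER_GEOMETRY
    cases = []
    for cont_type, centre in (("round_plate", (0.06, 0.01)), ("square_bowl", (-0.09, 0.05))):
        shape = "cylinder" if cont_type == "round_plate" else "box"
        cont = SolidSpec(shape, dict(geo[cont_type]), centre, cont_type)
        for fshape, dims in (
            ("cylinder", {"radius": 0.030, "height": 0.020}),
            ("box", {"size_x": 0.048, "size_y": 0.042, "height": 0.018}),
            ("spherical_cap", {"base_radius": 0.032, "height": 0.016}),
        ):
            cases.append((cont_type, fshape, cont, SolidSpec(fshape, dims, centre, "side_dish")))
    bowl = SolidSpec("cylinder", dict(geo["soup_bowl"]), (-0.14, -0.08), "soup_bowl")
    cases.append(("soup_bowl", "spherical_cap", bowl, fill_spec_for_bowl(bowl, "soup", 0.020)))
    glass = SolidSpec("cylinder", dict(geo["glass"]), (-0.14, 0.10), "glass")
    cases.append(("glass", "cylinder", glass, fill_spec_for_glass(glass, "dessert", 0.030)))
    return cases


def _estimate_case(cont_type, cont, food, k, noise, seed):
    spec = SceneSpec(
        containers=[cont], foods=[food], intrinsics=k, rgb_noise_sigma=0,
        noise_sigma_mm=noise, dropout=0.02 if noise else 0.0,
        liquid_dropout=0.15 if noise else 0.0, seed=seed,
    )
    frame, gt = render_scene(spec)
    cloud = depth_to_cloud(frame, k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        surf = reconstruct_plate_surface(cloud, gt.plate_mask, gt.food_mask, cont_type, k)
        cv = estimate_food_volume(cloud, gt.food_mask, surf, food.category, k)
    return cv.volume_ml / analytic_volume(food) - 1.0


def volumetry_benchmark(seed: int, n_noise_seeds: int = 20, noise_sigma_mm: float = 2.0) -> dict:
    """Relative volume error per (shape, container), noiseless and noisy."""
    k = SYNTHETIC_INTRINSICS
    noiseless = {}
    noisy_medians = {}
    for cont_type, fshape, cont, food in _volumetry_cases():
        key = f"{fshape}@{cont_type}"
        noiseless[key] = _estimate_case(cont_type, cont, food, k, 0.0, seed)
        errs = [
            abs(_estimate_case(cont_type, cont, food, k, noise_sigma_mm, seed + 1 + i))
            for i in range(n_noise_seeds)
        ]
        noisy_medians[key] = float(np.median(errs))
    return {
        "noiseless_rel_err": noiseless,
        "noiseless_max_abs_pct": 100.0 * max(abs(v) for v in noiseless.values()),
        "noisy_median_rel_err": noisy_medians,
        "noisy_max_median_pct": 100.0 * max(noisy_medians.values()),
    }


# --------------------------------------------------------------------------
# 3. consumed-fraction recovery on before/after pairs


def fraction_benchmark(
    seed: int,
    n_pairs: int = 30,
    noise_sigma_mm: float = 2.0,
) -> dict:
    """Fraction recovery with ground-truth masks, noiseless and noisy."""
    from .synthetic_scene import sample_fractions

    k = SYNTHETIC_INTRINSICS
    results = {}
    for label, noise in (("noiseless", 0.0), ("noisy", noise_sigma_mm)):
        rng = np.random.default_rng(seed)
        errs = []
        for _ in range(n_pairs):
            spec = random_scene(
                rng, intrinsics=k, noise_sigma_mm=noise,
                dropout=0.02 if noise else 0.0, liquid_dropout=0.15 if noise else 0.0,
            )
            cats = [f.category for f in spec.foods]
            fractions = sample_fractions(rng, cats)
            before, after, gt = make_before_after_pair(spec, fractions)
            mb = SegMaskPair(gt.before.food_mask, gt.before.plate_mask)
            ma = SegMaskPair(gt.after.food_mask, gt.after.plate_mask)
            menu = {c: NutrientVector(200, 20, 10, 8, 4) for c in cats}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec = estimate_meal(before, after, mb, ma, menu, MEAL_SIZES["normal"], k)
            for c in cats:
                if c in rec.fractions:
                    errs.append(abs(rec.fractions[c] - gt.fractions[c]))
        results[label] = {
            "n": len(errs),
            "max_abs_err": float(np.max(errs)),
            "median_abs_err": float(np.median(errs)),
        }
    return results


# --------------------------------------------------------------------------
# 4. desk-scale segmentation study


def _seg_scenes(n, seed, k, style):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        frame, gt = render_scene(random_scene(rng, intrinsics=k, style=style))
        out.append((frame.rgb, SegMaskPair(gt.food_mask, gt.plate_mask)))
    return out


def segmentation_benchmark(
    seed: int,
    n_train: int = 20,
    n_test: int = 5,
    epochs: int = 30,
    pretrain_epochs: int = 10,
    n_seeds: int = 3,
    width: int = 16,
    batch_size: int = 2,
) -> dict:
    """Train the encoder-PSPNet dual-head at desk scale and measure held-out
    food mean IoU, from scratch and with cross-style pretraining.

    The comparison holds total epochs fixed: ``epochs`` from scratch versus
    ``pretrain_epochs`` on style B followed by ``epochs - pretrain_epochs``
    of fine-tuning on style A, each over ``n_seeds`` weight seeds.
    """
    from .segmentation import SegModelConfig, build_model, evaluate_model, train_model

    k96 = SYNTHETIC_INTRINSICS.scaled(0.2)
    train_a = _seg_scenes(n_train, seed, k96, "A")
    train_b = _seg_scenes(n_train, seed + 1000, k96, "B")
    test_a = _seg_scenes(n_test, seed + 2000, k96, "A")

    scratch, pretrained = [], []
    for i in range(n_seeds):
        cfg = SegModelConfig(
            architecture="encoder_pspnet", with_plate_head=True, input_hw=(96, 128),
            epochs=epochs, batch_size=batch_size, seed=seed + i, width=width,
        )
        model = build_model(cfg)
        train_model(model, train_a, cfg)
        scratch.append(evaluate_model(model, test_a)["food_mean_iou"])

        cfg_p = replace(cfg, epochs=epochs - pretrain_epochs, pretrain_epochs=pretrain_epochs)
        model_p = build_model(cfg_p)
        train_model(model_p, train_a, cfg_p, pretrain_set=train_b)
        pretrained.append(evaluate_model(model_p, test_a)["food_mean_iou"])

    return {
        "scratch_miou": scratch,
        "pretrained_miou": pretrained,
        "scratch_median": float(np.median(scratch)),
        "pretrained_median": float(np.median(pretrained)),
    }


# --------------------------------------------------------------------------
# 5. method-comparison harness


def comparison_benchmark(seed: int, n_sets: int = 20, n_meals: int = 20) -> dict:
    """Energy MAE of per-component estimation vs the whole-meal SCP model."""
    from .evaluation import compare_methods, simulate_meal_sets

    rng = np.random.default_rng(seed)
    sets = simulate_meal_sets(rng, n_sets=n_sets, n_meals=n_meals)
    sys_mae, scp_mae = [], []
    for table, db, sizes in sets:
        reports = compare_methods(table, db, sizes)
        sys_mae.append(reports["system"].per_quantity["energy"]["mae"])
        scp_mae.append(reports["scp"].per_quantity["energy"]["mae"])
    sys_mae = np.asarray(sys_mae)
    scp_mae = np.asarray(scp_mae)
    return {
        "n_sets": n_sets,
        "system_energy_mae_median": float(np.median(sys_mae)),
        "scp_energy_mae_median": float(np.median(scp_mae)),
        "system_win_fraction": float(np.mean(sys_mae < scp_mae)),
    }
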