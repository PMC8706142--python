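"""Synthetic scene generator: analytic volumes, exact rendering, pairs."""

import numpy as np
import pytest
from scipy import integrate

from trayintake.labels import FOOD_LABELS, PLATE_LABELS
from trayintake.synthetic_scene import (
    CONTAINER_GEOMETRY,
    SYNTHETIC_INTRINSICS,
    SceneSpec,
    SolidSpec,
    analytic_volume,
    fill_spec_for_bowl,
    fill_spec_for_glass,
    generate_dataset,
    make_before_after_pair,
    random_scene,
    render_scene,
    strip_foods,
)

GEO = CONTAINER_GEOMETRY


def plate_at(centre=(0.05, 0.0)):
    return SolidSpec("cylinder", dict(GEO["round_plate"]), centre, "round_plate")


class TestAnalyticVolume:
    def test_cylinder_closed_form(self):
        s = SolidSpec("cylinder", {"radius": 0.030, "height": 0.020}, (0, 0), "side_dish")
        assert analytic_volume(s) == pytest.approx(np.pi * 900 * 20 / 1000, rel=1e-12)

    def test_box_volume(self):
        s = SolidSpec("box", {"size_x": 0.04, "size_y": 0.04, "height": 0.01}, (0, 0), "side_dish")
        assert analytic_volume(s) == pytest.approx(16.0)

    def test_spherical_cap_degenerate_limit(self):
        v = [
            analytic_volume(
                SolidSpec("spherical_cap", {"base_radius": 0.03, "height": h}, (0, 0), "dessert")
            )
            for h in (1e-3, 1e-5, 1e-7)
        ]
        assert v[0] > v[1] > v[2]
        assert v[2] < 1e-3

    @pytest.mark.parametrize(
        "shape,dims",
        [
            ("spherical_cap", {"base_radius": 0.032, "height": 0.017}),
            ("cone_frustum", {"radius_bottom": 0.03, "radius_top": 0.018, "height": 0.02}),
        ],
    )
    def test_curved_shapes_match_numerical_integration(self, shape, dims):
        """Closed forms vs an independent solid-of-revolution quadrature."""
        s = SolidSpec(shape, dims, (0, 0), "dessert")
        if shape == "spherical_cap":
            a, h = dims["base_radius"], dims["height"]
            R = (a**2 + h**2) / (2 * h)
            # radius^2 of the cap at height y above the base
            r2 = lambda y: R**2 - (R - h + y) ** 2  # noqa: E731
        else:
            r1, r2t, h = dims["radius_bottom"], dims["radius_top"], dims["height"]
            r2 = lambda y: (r1 + (r2t - r1) * y / h) ** 2  # noqa: E731
        v_num, _ = integrate.quad(lambda y: np.pi * r2(y), 0, dims["height"])
        assert analytic_volume(s) == pytest.approx(v_num * 1e6, rel=1e-8)


class TestRenderScene:
    def test_empty_tray_depth_is_camera_height(self, k_full):
        spec = SceneSpec(containers=[], foods=[], intrinsics=k_full, rgb_noise_sigma=0)
        frame, gt = render_scene(spec)
        assert np.allclose(gt.clean_depth_m, spec.tray_z)
        assert (gt.food_mask == 0).all() and (gt.plate_mask == 0).all()

    def test_same_seed_renders_identically(self, k_full):
        rng = np.random.default_rng(5)
        spec = random_scene(rng, intrinsics=k_full, noise_sigma_mm=2.0, dropout=0.02)
        f1, _ = render_scene(spec)
        f2, _ = render_scene(spec)
        assert np.array_equal(f1.depth, f2.depth)
        assert np.array_equal(f1.rgb, f2.rgb)

    def test_masks_follow_label_tables(self, k_full):
        rng = np.random.default_rng(6)
        frame, gt = render_scene(random_scene(rng, intrinsics=k_full))
        assert set(np.unique(gt.food_mask)) <= set(FOOD_LABELS.values())
        assert set(np.unique(gt.plate_mask)) <= set(PLATE_LABELS.values())
        # containers not covered by food carry the food-head plate label
        containers_visible = gt.plate_mask > 0
        assert (gt.food_mask[containers_visible] == FOOD_LABELS["plate"]).all()

    def test_rendered_volume_converges_to_analytic(self, k_full):
        """Depth-integral of the rendered cylinder vs closed form, two resolutions."""
        food = SolidSpec("cylinder", {"radius": 0.030, "height": 0.020}, (0.05, 0.0), "side_dish")

        def rendered_volume(k):
            spec = SceneSpec(containers=[plate_at()], foods=[food], intrinsics=k, rgb_noise_sigma=0)
            frame, gt = render_scene(spec)
            mask = gt.food_mask == FOOD_LABELS["side_dish"]
            zf = gt.clean_depth_m[mask]
            zp = spec.tray_z - GEO["round_plate"]["height"]
            # column height x pixel footprint area at the pixel's depth
            vol = np.sum((zp - zf) * zf**2 / (k.fx * k.fy)) * 1e6
            return vol

        va = analytic_volume(food)
        err_full = abs(rendered_volume(k_full) / va - 1)
        err_half = abs(rendered_volume(k_full.scaled(0.5)) / va - 1)
        assert err_full < 0.02
        assert err_full <= err_half + 0.01

    def test_out_of_frustum_food_warns_and_flags(self, k_full):
        plate = plate_at((0.0, 0.0))
        food = SolidSpec("cylinder", {"radius": 0.02, "height": 0.01}, (0.09, 0.0), "side_dish")
        spec = SceneSpec(containers=[plate], foods=[food], intrinsics=k_full.scaled(0.05))
        # shrink the view so the plate edge (and food) leave the frame
        spec2 = SceneSpec(
            containers=[SolidSpec("cylinder", dict(GEO["round_plate"]), (0.9, 0.0), "round_plate")],
            foods=[SolidSpec("cylinder", {"radius": 0.02, "height": 0.01}, (0.9, 0.0), "side_dish")],
            intrinsics=k_full,
        )
        with pytest.warns(UserWarning, match="frustum"):
            _, gt = render_scene(spec2)
        assert gt.in_frustum["side_dish"] is False

    def test_overlapping_containers_rejected(self, k_full):
        c1 = plate_at((0.0, 0.0))
        c2 = plate_at((0.05, 0.0))
        with pytest.raises(ValueError, match="overlap"):
            render_scene(SceneSpec(containers=[c1, c2], foods=[], intrinsics=k_full))


class TestBeforeAfterPair:
    def test_zero_fraction_preserves_geometry(self, k_full):
        spec = SceneSpec(
            containers=[plate_at()],
            foods=[SolidSpec("cylinder", {"radius": 0.03, "height": 0.02}, (0.05, 0.0), "side_dish")],
            intrinsics=k_full, rgb_noise_sigma=0,
        )
        before, after, gt = make_before_after_pair(spec, {"side_dish": 0.0})
        assert np.array_equal(before.depth, after.depth)

    def test_full_consumption_removes_food_keeps_container(self, k_full):
        bowl = SolidSpec("cylinder", dict(GEO["soup_bowl"]), (-0.1, 0.0), "soup_bowl")
        spec = SceneSpec(
            containers=[bowl], foods=[fill_spec_for_bowl(bowl, "soup", 0.02)],
            intrinsics=k_full, rgb_noise_sigma=0,
        )
        _, _, gt = make_before_after_pair(spec, {"soup": 1.0})
        assert FOOD_LABELS["soup"] not in np.unique(gt.after.food_mask)
        assert PLATE_LABELS["soup_bowl"] in np.unique(gt.after.plate_mask)

    def test_cylinder_half_fraction_halves_height(self, k_full):
        spec = SceneSpec(
            containers=[plate_at()],
            foods=[SolidSpec("cylinder", {"radius": 0.03, "height": 0.02}, (0.05, 0.0), "side_dish")],
            intrinsics=k_full, rgb_noise_sigma=0,
        )
        before, after, gt = make_before_after_pair(spec, {"side_dish": 0.5})
        top_before = gt.before.clean_depth_m.min()
        top_after = gt.after.clean_depth_m.min()
        # top surface drops by half the original height
        assert (top_after - top_before) == pytest.approx(0.010, abs=1e-9)

    @pytest.mark.parametrize("frac", [0.25, 0.5, 0.8, 1.0])
    def test_remaining_volume_matches_requested_fraction(self, k_full, frac):
        rng = np.random.default_rng(11)
        spec = random_scene(rng, intrinsics=k_full)
        cats = [f.category for f in spec.foods]
        _, _, gt = make_before_after_pair(spec, {c: frac for c in cats})
        for c in cats:
            vb, va = gt.volumes_before_ml[c], gt.volumes_after_ml[c]
            assert 1 - va / vb == pytest.approx(frac, abs=1e-6)

    def test_unknown_category_fraction_rejected(self, k_full):
        spec = SceneSpec(containers=[plate_at()], foods=[], intrinsics=k_full)
        with pytest.raises(ValueError, match="not in scene"):
            make_before_after_pair(spec, {"soup": 0.5})

    def test_fill_levels_respect_cavity_depth(self):
        bowl = SolidSpec("cylinder", dict(GEO["soup_bowl"]), (0, 0), "soup_bowl")
        with pytest.raises(ValueError):
            fill_spec_for_bowl(bowl, "soup", 0.05)
        glass = SolidSpec("cylinder", dict(GEO["glass"]), (0, 0), "glass")
        with pytest.raises(ValueError):
            fill_spec_for_glass(glass, "dessert", 0.06)


class TestGeneratedDataset:
    def test_dataset_tree_and_reproducibility(self, tmp_path, k96):
        from trayintake.menu_db import load_menu_db
        from trayintake.synthetic_scene import read_mask

        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        generate_dataset(2, seed=9, out_dir=d1, intrinsics=k96)
        generate_dataset(2, seed=9, out_dir=d2, intrinsics=k96)
        for name in ("menu.csv", "index.json"):
            assert (d1 / name).exists()
        m1 = read_mask(d1 / "scene_000" / "before_food_mask.png")
        m2 = read_mask(d2 / "scene_000" / "before_food_mask.png")
        assert np.array_equal(m1, m2)
        db = load_menu_db(d1 / "menu.csv")
        assert len(db) == 2
        # every placed category has a menu entry
        import json

        gt = json.loads((d1 / "scene_000" / "gt.json").read_text())
        menu = db.lookup(gt["date"], gt["variant"])
        assert set(gt["fractions"]) <= menu.categories

    def test_rejects_zero_scenes(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(0, seed=1, out_dir=tmp_path)


def test_strip_foods_keeps_containers(k_full):
    rng = np.random.default_rng(3)
    spec = random_scene(rng, intrinsics=k_full)
    bare = strip_foods(spec)
    assert bare.foods == [] and bare.containers == spec.containers
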