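"""Volumetry: surface reconstruction, volume integration, fractions, intake."""

import warnings

import numpy as np
import pytest

from trayintake.labels import SegMaskPair
from trayintake.menu_db import MEAL_SIZES, NutrientVector
from trayintake.rgbd_io import depth_to_cloud
from trayintake.synthetic_scene import (
    CONTAINER_GEOMETRY,
    SceneSpec,
    SolidSpec,
    analytic_volume,
    fill_spec_for_bowl,
    make_before_after_pair,
    render_scene,
)
from trayintake.volume_intake import (
    CategoryVolume,
    InvalidSurfaceError,
    VolumeEstimate,
    compute_intake,
    consumed_fraction,
    estimate_food_volume,
    estimate_meal,
    reconstruct_plate_surface,
    snap_fraction,
)

GEO = CONTAINER_GEOMETRY


def render_with_cloud(containers, foods, k, **kw):
    spec = SceneSpec(containers=containers, foods=foods, intrinsics=k, rgb_noise_sigma=0, **kw)
    frame, gt = render_scene(spec)
    return spec, frame, gt, depth_to_cloud(frame, k)


class TestPlateSurface:
    def test_empty_flat_plate_reconstructed_within_1mm(self, k_full):
        plate = SolidSpec("cylinder", dict(GEO["round_plate"]), (0.04, 0.01), "round_plate")
        spec, frame, gt, cloud = render_with_cloud([plate], [], k_full)
        surf = reconstruct_plate_surface(cloud, gt.plate_mask, gt.food_mask, "round_plate", k_full)
        z = surf.z_map(k_full)
        region = gt.plate_mask == 1
        # compare against the rendered depths over the plate top
        diff = np.abs(z[region] - gt.clean_depth_m[region])
        assert np.median(diff) < 0.001

    def test_under_box_heights_match_plate_plane(self, k_full):
        plate = SolidSpec("cylinder", dict(GEO["round_plate"]), (0.0, 0.0), "round_plate")
        box = SolidSpec("box", {"size_x": 0.10, "size_y": 0.08, "height": 0.02}, (0.0, 0.0), "side_dish")
        spec, frame, gt, cloud = render_with_cloud([plate], [box], k_full)
        surf = reconstruct_plate_surface(cloud, gt.plate_mask, gt.food_mask, "round_plate", k_full)
        z = surf.z_map(k_full)
        under = gt.food_mask == 3
        true_plane = spec.tray_z - GEO["round_plate"]["height"]
        assert np.abs(z[under] - true_plane).max() < 0.002

    def test_fully_occluded_container_raises(self, k_full):
        plate = SolidSpec("cylinder", dict(GEO["round_plate"]), (0.0, 0.0), "round_plate")
        spec, frame, gt, cloud = render_with_cloud([plate], [], k_full)
        empty_plate_mask = np.zeros_like(gt.plate_mask)
        with pytest.raises(InvalidSurfaceError):
            reconstruct_plate_surface(cloud, empty_plate_mask, gt.food_mask, "round_plate", k_full)

    def test_bowl_cavity_sphere_recovered(self, k_full):
        bowl = SolidSpec("cylinder", dict(GEO["soup_bowl"]), (-0.1, -0.05), "soup_bowl")
        spec, frame, gt, cloud = render_with_cloud([bowl], [], k_full)
        surf = reconstruct_plate_surface(cloud, gt.plate_mask, gt.food_mask, "soup_bowl", k_full)
        assert surf.method == "sphere_fit"
        # cavity bottom: rim - cavity_depth
        true_bottom = spec.tray_z - (GEO["soup_bowl"]["height"] - GEO["soup_bowl"]["cavity_depth"])
        model_bottom = surf.model.cz + surf.model.radius
        assert model_bottom == pytest.approx(true_bottom, abs=0.002)


class TestFoodVolume:
    @pytest.mark.parametrize(
        "shape,dims",
        [
            ("cylinder", {"radius": 0.030, "height": 0.020}),
            ("box", {"size_x": 0.048, "size_y": 0.042, "height": 0.018}),
            ("spherical_cap", {"base_radius": 0.032, "height": 0.016}),
        ],
    )
    def test_noiseless_solids_within_five_percent(self, k_full, shape, dims):
        centre = (0.05, 0.01)
        plate = SolidSpec("cylinder", dict(GEO["round_plate"]), centre, "round_plate")
        food = SolidSpec(shape, dims, centre, "side_dish")
        spec, frame, gt, cloud = render_with_cloud([plate], [food], k_full)
        surf = reconstruct_plate_surface(cloud, gt.plate_mask, gt.food_mask, "round_plate", k_full)
        cv = estimate_food_volume(cloud, gt.food_mask, surf, "side_dish", k_full)
        assert cv.volume_ml == pytest.approx(analytic_volume(food), rel=0.05)

    def test_zero_height_food_gives_zero_volume(self, k_full):
        """Food surface equal to the plate surface integrates to ~0."""
        plate = SolidSpec("cylinder", dict(GEO["round_plate"]), (0.0, 0.0), "round_plate")
        spec, frame, gt, cloud = render_with_cloud([plate], [], k_full)
        surf = reconstruct_plate_surface(cloud, gt.plate_mask, gt.food_mask, "round_plate", k_full)
        fake_food = np.where(gt.plate_mask == 1, 3, 0).astype(np.uint8)
        cv = estimate_food_volume(cloud, fake_food, surf, "side_dish", k_full)
        assert cv.volume_ml < 2.0  # quantisation-level residual only

    def test_missing_depth_flagged_low_confidence(self, k_full):
        centre = (0.05, 0.0)
        plate = SolidSpec("cylinder", dict(GEO["round_plate"]), centre, "round_plate")
        food = SolidSpec("cylinder", {"radius": 0.03, "height": 0.02}, centre, "side_dish")
        spec, frame, gt, cloud = render_with_cloud([plate], [food], k_full)
        region = gt.food_mask == 3
        # knock out 60% of the food region's depth
        rng = np.random.default_rng(0)
        kill = region & (rng.uniform(size=region.shape) < 0.6)
        frame.depth[kill] = 0
        cloud2 = depth_to_cloud(frame, k_full)
        surf = reconstruct_plate_surface(cloud2, gt.plate_mask, gt.food_mask, "round_plate", k_full)
        cv = estimate_food_volume(cloud2, gt.food_mask, surf, "side_dish", k_full)
        assert cv.low_confidence
        assert cv.missing_fraction > 0.5
        # nearest-neighbour fill keeps the estimate close regardless
        assert cv.volume_ml == pytest.approx(analytic_volume(food), rel=0.10)

    def test_absent_category_rejected(self, k_full):
        plate = SolidSpec("cylinder", dict(GEO["round_plate"]), (0.0, 0.0), "round_plate")
        spec, frame, gt, cloud = render_with_cloud([plate], [], k_full)
        surf = reconstruct_plate_surface(cloud, gt.plate_mask, gt.food_mask, "round_plate", k_full)
        with pytest.raises(ValueError, match="absent"):
            estimate_food_volume(cloud, gt.food_mask, surf, "soup", k_full)

    def test_shrinking_never_increases_volume(self, k_full):
        """Monotonicity: smaller items never estimate larger (noiseless)."""
        centre = (0.05, 0.0)
        plate = SolidSpec("cylinder", dict(GEO["round_plate"]), centre, "round_plate")
        vols = []
        for h in (0.024, 0.016, 0.008):
            food = SolidSpec("cylinder", {"radius": 0.03, "height": h}, centre, "side_dish")
            spec, frame, gt, cloud = render_with_cloud([plate], [food], k_full)
            surf = reconstruct_plate_surface(cloud, gt.plate_mask, gt.food_mask, "round_plate", k_full)
            vols.append(estimate_food_volume(cloud, gt.food_mask, surf, "side_dish", k_full).volume_ml)
        assert vols[0] > vols[1] > vols[2]


class TestConsumedFraction:
    def _ve(self, phase, **vols):
        est = VolumeEstimate(phase=phase)
        for c, v in vols.items():
            est.volumes[c] = CategoryVolume(c, v, 100)
        return est

    def test_equal_volumes_give_zero(self):
        assert consumed_fraction(self._ve("before", soup=50), self._ve("after", soup=50), "soup") == 0.0

    def test_missing_after_category_is_fully_consumed(self):
        assert consumed_fraction(self._ve("before", soup=50), self._ve("after"), "soup") == 1.0

    def test_direct_formula(self):
        f = consumed_fraction(self._ve("before", soup=100), self._ve("after", soup=40), "soup")
        assert f == pytest.approx(0.6)

    def test_noise_inflated_after_volume_clamps_to_zero(self):
        f = consumed_fraction(self._ve("before", soup=100), self._ve("after", soup=110), "soup")
        assert f == 0.0

    def test_category_absent_from_before_rejected(self):
        with pytest.raises(KeyError):
            consumed_fraction(self._ve("before"), self._ve("after", soup=10), "soup")


class TestComputeIntake:
    def test_full_consumption_recovers_meal_totals(self):
        menu = {"soup": NutrientVector(150, 10, 5, 3, 1), "dessert": NutrientVector(100, 20, 4, 2, 1)}
        rec = compute_intake({"soup": 1.0, "dessert": 1.0}, menu)
        assert rec.totals.energy == 250

    def test_sauce_excluded_from_totals(self):
        menu = {"side_dish": NutrientVector(200), "sauce": NutrientVector(50)}
        rec = compute_intake({"side_dish": 0.5, "sauce": 1.0}, menu)
        assert rec.totals.energy == pytest.approx(100.0)
        assert rec.intakes["sauce"].energy == pytest.approx(50.0)  # recorded, not totalled

    def test_chained_fraction_and_size_scaling(self):
        from trayintake.menu_db import scale_nutrients

        soup = NutrientVector(150, 0, 10, 0, 0)
        scaled = {"soup": scale_nutrients(soup, MEAL_SIZES["reduced"])}
        rec = compute_intake({"soup": 0.6}, scaled)
        assert rec.totals.energy == pytest.approx(60.0)
        assert rec.totals.protein == pytest.approx(4.0)

    def test_unknown_category_rejected(self):
        with pytest.raises(KeyError):
            compute_intake({"soup": 1.0}, {"dessert": NutrientVector(100)})

    def test_intake_linear_in_fraction_and_size(self):
        nv = NutrientVector(300, 30, 15, 9, 4)
        for size in MEAL_SIZES.values():
            from trayintake.menu_db import scale_nutrients

            menu = {"soup": scale_nutrients(nv, size)}
            e1 = compute_intake({"soup": 0.25}, menu).totals.energy
            e2 = compute_intake({"soup": 0.50}, menu).totals.energy
            assert e2 == pytest.approx(2 * e1)
            assert e1 == pytest.approx(300 * float(size.factor) * 0.25)


class TestEstimateMeal:
    def test_full_pipeline_recovers_fractions_and_intake(self, k_full):
        bowl = SolidSpec("cylinder", dict(GEO["soup_bowl"]), (-0.13, -0.06), "soup_bowl")
        plate = SolidSpec("cylinder", dict(GEO["round_plate"]), (0.07, 0.01), "round_plate")
        foods = [
            fill_spec_for_bowl(bowl, "soup", 0.022),
            SolidSpec("cylinder", {"radius": 0.028, "height": 0.016}, (0.07, 0.01), "meat_fish"),
        ]
        spec = SceneSpec(containers=[bowl, plate], foods=foods, intrinsics=k_full, rgb_noise_sigma=0)
        fractions = {"soup": 0.7, "meat_fish": 0.3}
        before, after, gt = make_before_after_pair(spec, fractions)
        mb = SegMaskPair(gt.before.food_mask, gt.before.plate_mask)
        ma = SegMaskPair(gt.after.food_mask, gt.after.plate_mask)
        menu = {"soup": NutrientVector(150, 10, 5, 3, 1), "meat_fish": NutrientVector(180, 0, 26, 8, 3)}
        rec = estimate_meal(before, after, mb, ma, menu, MEAL_SIZES["normal"], k_full)
        for c, f in fractions.items():
            assert rec.fractions[c] == pytest.approx(f, abs=0.03)
        expected = 150 * rec.fractions["soup"] + 180 * rec.fractions["meat_fish"]
        assert rec.totals.energy == pytest.approx(expected)

    def test_pipeline_deterministic(self, k_full):
        bowl = SolidSpec("cylinder", dict(GEO["soup_bowl"]), (-0.13, -0.06), "soup_bowl")
        spec = SceneSpec(
            containers=[bowl], foods=[fill_spec_for_bowl(bowl, "soup", 0.02)],
            intrinsics=k_full, rgb_noise_sigma=0,
        )
        before, after, gt = make_before_after_pair(spec, {"soup": 0.4})
        mb = SegMaskPair(gt.before.food_mask, gt.before.plate_mask)
        ma = SegMaskPair(gt.after.food_mask, gt.after.plate_mask)
        menu = {"soup": NutrientVector(150)}
        r1 = estimate_meal(before, after, mb, ma, menu, MEAL_SIZES["normal"], k_full)
        r2 = estimate_meal(before, after, mb, ma, menu, MEAL_SIZES["normal"], k_full)
        assert r1.fractions == r2.fractions
        assert r1.totals == r2.totals


def test_snap_fraction_grids():
    assert snap_fraction(0.63) == pytest.approx(0.6)
    assert snap_fraction(0.63, step=0.25) == pytest.approx(0.75)
    assert snap_fraction(1.04) == 1.0
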