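"""Method-comparison harness: references, error statistics, significance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trayintake.evaluation import (
    ALL,
    EstimateTable,
    compare_methods,
    intake_from_fractions,
    mae_mre,
    paired_t_test,
    pearson_r,
    per_category_error,
    reference_fractions,
    simulate_meal_sets,
)
from trayintake.menu_db import MEAL_SIZES, NutrientVector


def table_from(rows):
    return EstimateTable(pd.DataFrame(rows, columns=["meal_id", "method", "category", "fraction"]))


class TestReferenceFractions:
    def test_mean_of_three_raters(self):
        t = table_from([("m1", f"rater_{i}", "soup", f) for i, f in ((1, 0.4), (2, 0.5), (3, 0.6))])
        assert reference_fractions(t)[("m1", "soup")] == pytest.approx(0.5)

    def test_single_rater_passthrough(self):
        t = table_from([("m1", "rater_1", "soup", 0.7)])
        assert reference_fractions(t)[("m1", "soup")] == pytest.approx(0.7)

    def test_coarse_grid_raters(self):
        t = table_from([("m1", f"rater_{i}", "soup", f) for i, f in ((1, 0.50), (2, 0.50), (3, 0.75))])
        assert reference_fractions(t)[("m1", "soup")] == pytest.approx(0.58333, abs=1e-4)

    def test_no_raters_rejected(self):
        with pytest.raises(ValueError, match="no rater"):
            reference_fractions(table_from([("m1", "system", "soup", 0.5)]))


class TestEstimateTableValidation:
    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            table_from([("m1", "rater_1", "soup", 1.2)])

    def test_scp_must_be_single_whole_meal_row(self):
        with pytest.raises(ValueError, match="scp"):
            table_from([("m1", "scp", "soup", 0.5)])
        with pytest.raises(ValueError, match="scp"):
            table_from([("m1", "scp", ALL, 0.5), ("m1", "scp", ALL, 0.6)])


MENU = {
    "soup": NutrientVector(150, 10, 5, 3, 1),
    "dessert": NutrientVector(100, 20, 4, 2, 1),
    "sauce": NutrientVector(50, 5, 1, 3, 1),
}


class TestIntakeFromFractions:
    def test_whole_meal_full_fraction_equals_totals(self):
        nv = intake_from_fractions({ALL: 1.0}, MENU, MEAL_SIZES["normal"], mode="whole_meal")
        assert nv.energy == 250  # sauce excluded from the shared basis

    def test_modes_agree_for_equal_fractions(self):
        f = 0.4
        per = intake_from_fractions(
            {"soup": f, "dessert": f, "sauce": f}, MENU, MEAL_SIZES["normal"]
        )
        whole = intake_from_fractions({ALL: f}, MENU, MEAL_SIZES["normal"], mode="whole_meal")
        assert per.energy == pytest.approx(whole.energy)

    def test_per_component_hand_example(self):
        nv = intake_from_fractions(
            {"soup": 1.0, "dessert": 0.0}, MENU, MEAL_SIZES["normal"]
        )
        assert nv.energy == 150 and nv.protein == 5

    def test_size_factor_applies(self):
        nv = intake_from_fractions({"soup": 1.0}, MENU, MEAL_SIZES["doubly_reduced"])
        assert nv.energy == pytest.approx(50.0)


class TestMaeMre:
    def test_perfect_agreement(self):
        assert mae_mre(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        r = np.full(5, 100.0)
        mae, sd, mre = mae_mre(r + 10, r)
        assert (mae, mre) == (10.0, 10.0)
        assert sd == 0.0

    def test_hand_computation_two_meals(self):
        mae, sd, mre = mae_mre(np.array([100.0, 120.0]), np.array([100.0, 100.0]))
        assert mae == pytest.approx(10.0)
        assert sd == pytest.approx(14.1421, abs=1e-3)
        assert mre == pytest.approx(10.0)

    def test_scale_invariance_of_mre(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(50, 150, 10)
        e = r + rng.normal(0, 5, 10)
        _, _, mre1 = mae_mre(e, r)
        mae1, _, _ = mae_mre(e, r)
        mae3, _, mre3 = mae_mre(3 * e, 3 * r)
        assert mre3 == pytest.approx(mre1)
        assert mae3 == pytest.approx(3 * mae1)

    def test_zero_reference_flagged(self):
        with pytest.raises(ZeroDivisionError):
            mae_mre(np.array([1.0, 2.0]), np.array([0.0, 0.0]))

    def test_per_meal_ratio_variant(self):
        _, _, mre = mae_mre(
            np.array([110.0, 220.0]), np.array([100.0, 200.0]), per_meal_ratio=True
        )
        assert mre == pytest.approx(10.0)


class TestCorrelationAndTests:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_five_point_set_matches_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 9.0])
        r, p = pearson_r(x, y)
        rx = x - x.mean()
        ry = y - y.mean()
        expect = (rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum())
        assert r == pytest.approx(expect)

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_paired_t_antisymmetry_and_textbook_value(self):
        a = np.array([3.0, 5.0, 4.0, 6.0, 7.0, 5.5])
        b = np.array([2.5, 4.0, 4.5, 5.0, 6.5, 5.0])
        t1, p1 = paired_t_test(a, b)
        t2, p2 = paired_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t1 == pytest.approx(t_hand)
        assert p1 == pytest.approx(2 * stats.t.sf(abs(t_hand), len(d) - 1))

    def test_identical_pairs_flagged(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t_test(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestPerCategoryError:
    def test_self_comparison_is_zero(self):
        ref = {("m1", "soup"): 0.4, ("m1", "dessert"): 0.9}
        assert per_category_error(dict(ref), ref) == {"dessert": 0.0, "soup": 0.0}

    def test_whole_meal_fraction_compared_to_each_component(self):
        ref = {("m1", "soup"): 0.2, ("m1", "dessert"): 0.8}
        scp = {("m1", ALL): 0.5}
        out = per_category_error(scp, ref)
        assert out == {"dessert": pytest.approx(30.0), "soup": pytest.approx(30.0)}

    def test_one_meal_toy_table_hand_computation(self):
        ref = {("m1", "soup"): 0.5, ("m2", "soup"): 0.9}
        est = {("m1", "soup"): 0.6, ("m2", "soup"): 0.7}
        assert per_category_error(est, ref)["soup"] == pytest.approx(15.0)


class TestCompareMethods:
    def test_fully_consumed_meals_make_methods_coincide(self):
        """When every fraction is 1, system, SCP and reference agree exactly."""
        rows = []
        for meal in ("m1", "m2"):
            for cat in ("soup", "dessert"):
                for r in (1, 2, 3):
                    rows.append((meal, f"rater_{r}", cat, 1.0))
                rows.append((meal, "system", cat, 1.0))
            rows.append((meal, "scp", ALL, 1.0))
        # two meals with different menus via the simulation helper's layout
        import datetime as dt

        from trayintake.menu_db import DishComponent, Menu, MenuDatabase

        db = MenuDatabase()
        sizes = {}
        for i, meal in enumerate(("m1", "m2")):
            date = dt.date(2021, 3, 1 + i)
            db.add(Menu(date, "A", (
                DishComponent("s", "soup", 1, "portions", NutrientVector(150 + 10 * i)),
                DishComponent("d", "dessert", 1, "portions", NutrientVector(100)),
            )))
            sizes[meal] = (date, "A", "normal")
        reports = compare_methods(table_from(rows), db, sizes)
        for method in ("system", "scp"):
            q = reports[method].per_quantity["energy"]
            assert q["mae"] == pytest.approx(0.0, abs=1e-9)

    def test_simulated_sets_favour_per_component(self):
        rng = np.random.default_rng(12)
        sets = simulate_meal_sets(rng, n_sets=5, n_meals=15)
        wins = 0
        for table, db, sizes in sets:
            reports = compare_methods(table, db, sizes)
            wins += (
                reports["system"].per_quantity["energy"]["mae"]
                < reports["scp"].per_quantity["energy"]["mae"]
            )
        assert wins >= 4  # directional sanity, mirrors the clinical finding

    def test_plot_export_writes_files(self, tmp_path):
        rng = np.random.default_rng(1)
        table, db, sizes = simulate_meal_sets(rng, n_sets=1, n_meals=8)[0]
        compare_methods(table, db, sizes, plot_dir=tmp_path)
        assert (tmp_path / "energy_bars.png").exists()
        assert (tmp_path / "energy_differences_box.png").exists()
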