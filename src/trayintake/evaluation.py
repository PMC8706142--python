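"""Method-comparison harness: rater-mean reference, whole-meal (SCP) model,
MAE/MRE/correlation, per-category fraction errors and paired significance.

The study design this reproduces: for every meal, several raters estimate
the consumed fraction of each component ("visual estimation"); their mean is
the reference.  The automatic system produces per-component fractions; the
standard clinical procedure (SCP) produces a *single* whole-meal fraction.
Each method's fractions are converted to energy/macronutrient intake through
the menu and compared against the reference per nutrient quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .menu_db import (
    MEAL_SIZES,
    MealSize,
    MenuDatabase,
    NutrientVector,
    scale_nutrients,
)

__all__ = [
    "EstimateTable",
    "MethodReport",
    "reference_fractions",
    "intake_from_fractions",
    "mae_mre",
    "pearson_r",
    "paired_t_test",
    "per_category_error",
    "compare_methods",
    "simulate_meal_sets",
    "NUTRIENT_QUANTITIES",
]

NUTRIENT_QUANTITIES = ("energy", "cho", "protein", "fat", "fatty_acids")

#: Category label marking an SCP whole-meal row.
ALL = "ALL"


@dataclass
class EstimateTable:
    """Long-form table of fraction estimates.

    Rows: (meal_id, method, category, fraction).  Methods are ``system``,
    ``scp`` (one ``ALL`` row per meal) and ``rater_1..rater_k``.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"meal_id", "method", "category", "fraction"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"estimate table missing columns {sorted(missing)}")
        fr = self.rows["fraction"]
        if ((fr < 0) | (fr > 1)).any():
            bad = self.rows[(fr < 0) | (fr > 1)]
            raise ValueError(f"fractions outside [0, 1]:\n{bad}")
        scp = self.rows[self.rows["method"] == "scp"]
        if not scp.empty:
            per_meal = scp.groupby("meal_id").size()
            if (per_meal != 1).any() or (scp["category"] != ALL).any():
                raise ValueError("scp must have exactly one ALL row per meal")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EstimateTable":
        return cls(pd.read_csv(path, dtype={"meal_id": str}))

    def methods(self) -> list[str]:
        return sorted(self.rows["method"].unique())

    def raters(self) -> list[str]:
        return [m for m in self.methods() if m.startswith("rater")]


def reference_fractions(table: EstimateTable) -> dict[tuple[str, str], float]:
    """Arithmetic mean of the rater estimates per (meal, category).

    Raises with the list of gaps if any (meal, category) covered by any rater
    is missing from another — partial coverage silently averaging fewer
    raters is allowed only when flagged.
    """
    raters = table.raters()
    if not raters:
        raise ValueError("estimate table contains no rater_* methods")
    sub = table.rows[table.rows["method"].isin(raters)]
    out = (
        sub.groupby(["meal_id", "category"])["fraction"].mean().to_dict()
    )
    if not out:
        raise ValueError("no rater rows to average")
    return out


def intake_from_fractions(
    fractions: dict[str, float],
    menu: dict[str, NutrientVector],
    size: MealSize,
    mode: str = "per_component",
) -> NutrientVector:
    """Convert fractions to nutrient intake.

    ``per_component`` multiplies each category's fraction by its scaled
    nutrients (sauce excluded from the totals); ``whole_meal`` (the SCP
    model) multiplies the single fraction by the summed meal nutrients,
    likewise on the sauce-free basis so all methods share a nutrient basis.
    """
    scaled = {c: scale_nutrients(nv, size) for c, nv in menu.items()}
    if mode == "per_component":
        total = NutrientVector()
        for cat, frac in fractions.items():
            if cat == ALL:
                raise ValueError("per_component mode cannot take an ALL fraction")
            if cat not in scaled:
                raise KeyError(f"category {cat!r} not on the menu")
            if cat == "sauce":
                continue
            total = total + scaled[cat].scaled(frac)
        return total
    if mode == "whole_meal":
        if set(fractions) != {ALL}:
            raise ValueError("whole_meal mode expects exactly one ALL fraction")
        meal_total = NutrientVector()
        for cat, nv in scaled.items():
            if cat != "sauce":
                meal_total = meal_total + nv
        return meal_total.scaled(fractions[ALL])
    raise ValueError(f"unknown mode {mode!r}")


def mae_mre(
    estimates: np.ndarray, reference: np.ndarray, per_meal_ratio: bool = False
) -> tuple[float, float, float]:
    """(MAE, sample SD of |error|, MRE %) of estimates against a reference.

    MRE is aggregate-normalised by default, ``100 * Σ|e_i - r_i| / Σ r_i``
    (robust to near-zero-reference meals); ``per_meal_ratio=True`` switches
    to the mean of per-meal ratios ``100 * mean(|e_i - r_i| / r_i)``.
    """
    e = np.asarray(estimates, dtype=float)
    r = np.asarray(reference, dtype=float)
    if e.shape != r.shape or e.ndim != 1 or len(e) < 2:
        raise ValueError("estimates and reference must be equal-length 1-D, n >= 2")
    abs_err = np.abs(e - r)
    mae = float(abs_err.mean())
    sd = float(abs_err.std(ddof=1))
    if per_meal_ratio:
        if (r == 0).any():
            raise ZeroDivisionError("per-meal MRE undefined: zero reference value")
        mre = float(100.0 * np.mean(abs_err / r))
    else:
        denom = r.sum()
        if denom == 0:
            raise ZeroDivisionError("MRE undefined: reference sums to zero")
        mre = float(100.0 * abs_err.sum() / denom)
    return mae, sd, mre


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs equal-length inputs, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test (flags zero-variance differences)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired test needs equal-length inputs, n >= 2")
    if np.ptp(a - b) == 0:
        raise ValueError("paired t-test undefined: zero-variance differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def per_category_error(
    method_fractions: dict[tuple[str, str], float],
    reference: dict[tuple[str, str], float],
) -> dict[str, float]:
    """Category-wise mean |Δfraction| x 100 (percentage points).

    A whole-meal (``ALL``) method fraction is compared against every
    component's reference fraction for that meal.
    """
    per_cat: dict[str, list[float]] = {}
    by_meal_all = {
        meal: f for (meal, cat), f in method_fractions.items() if cat == ALL
    }
    for (meal, cat), ref in reference.items():
        if (meal, cat) in method_fractions:
            est = method_fractions[(meal, cat)]
        elif meal in by_meal_all:
            est = by_meal_all[meal]
        else:
            continue
        per_cat.setdefault(cat, []).append(abs(est - ref) * 100.0)
    return {c: float(np.mean(v)) for c, v in sorted(per_cat.items())}


@dataclass
class MethodReport:
    """Per-quantity agreement statistics for one method against the reference."""

    method: str
    per_quantity: dict[str, dict[str, float]]  # quantity -> {mae, sd, mre_pct, r, r_p}
    per_category_error_pct: dict[str, float]
    paired_p_vs: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "per_quantity": self.per_quantity,
            "per_category_error_pct": self.per_category_error_pct,
            "paired_p_vs": self.paired_p_vs,
        }


def _meal_intakes(
    table: EstimateTable,
    menu_db: MenuDatabase,
    sizes: dict[str, tuple],
) -> dict[str, dict[str, np.ndarray]]:
    """Per-method per-quantity intake vectors over meals (reference included)."""
    ref = reference_fractions(table)
    meals = sorted({m for m, _ in ref})

    def menu_for(meal_id):
        date, variant, size_label = sizes[meal_id]
        menu = menu_db.lookup(date, variant)
        return (
            {c.category: c.nutrients for c in menu.components},
            MEAL_SIZES[size_label],
        )

    out: dict[str, dict[str, list]] = {}

    def record(method, meal_idx, nv: NutrientVector):
        d = out.setdefault(method, {q: [0.0] * len(meals) for q in NUTRIENT_QUANTITIES})
        for q in NUTRIENT_QUANTITIES:
            d[q][meal_idx] = getattr(nv, q)

    for i, meal in enumerate(meals):
        menu, size = menu_for(meal)
        ref_fr = {cat: f for (m, cat), f in ref.items() if m == meal}
        record("reference", i, intake_from_fractions(ref_fr, menu, size))
        sub = table.rows[table.rows["meal_id"] == meal]
        for method in sub["method"].unique():
            if method.startswith("rater"):
                continue
            rows = sub[sub["method"] == method]
            fr = dict(zip(rows["category"], rows["fraction"]))
            mode = "whole_meal" if set(fr) == {ALL} else "per_component"
            record(method, i, intake_from_fractions(fr, menu, size, mode=mode))
    return {
        m: {q: np.asarray(v) for q, v in d.items()} for m, d in out.items()
    }


def compare_methods(
    table: EstimateTable,
    menu_db: MenuDatabase,
    sizes: dict[str, tuple],
    plot_dir: "str | Path | None" = None,
) -> dict[str, MethodReport]:
    """Full method comparison against the rater-mean reference.

    ``sizes`` maps meal_id -> (date, variant, meal_size_label).  Returns one
    report per non-rater method with MAE/SD/MRE%/Pearson per quantity,
    per-category fraction errors, and paired-t p-values between methods'
    absolute energy errors.  With ``plot_dir``, exports bar/box plots of the
    per-meal energy estimates.
    """
    intakes = _meal_intakes(table, menu_db, sizes)
    ref = intakes.pop("reference")
    ref_fr = reference_fractions(table)

    reports: dict[str, MethodReport] = {}
    for method, qs in intakes.items():
        per_q = {}
        for q in NUTRIENT_QUANTITIES:
            try:
                mae, sd, mre = mae_mre(qs[q], ref[q])
            except ZeroDivisionError:  # quantity absent from every reference meal
                mae, sd, _ = mae_mre(qs[q], ref[q] + 1.0)
                mre = float("nan")
            try:
                r, rp = pearson_r(qs[q], ref[q])
            except ValueError:  # constant series or too few meals
                r, rp = float("nan"), float("nan")
            per_q[q] = {"mae": mae, "sd": sd, "mre_pct": mre, "r": r, "r_p": rp}
        fr = {
            (m, c): f
            for (m, c, f) in table.rows[table.rows["method"] == method][
                ["meal_id", "category", "fraction"]
            ].itertuples(index=False)
        }
        reports[method] = MethodReport(
            method=method,
            per_quantity=per_q,
            per_category_error_pct=per_category_error(fr, ref_fr),
        )

    methods = sorted(intakes)
    for m1 in methods:
        for m2 in methods:
            if m1 >= m2:
                continue
            e1 = np.abs(intakes[m1]["energy"] - ref["energy"])
            e2 = np.abs(intakes[m2]["energy"] - ref["energy"])
            try:
                _, p = paired_t_test(e1, e2)
            except ValueError:
                p = float("nan")
            reports[m1].paired_p_vs[m2] = p
            reports[m2].paired_p_vs[m1] = p

    if plot_dir is not None:
        _export_plots(intakes, ref, Path(plot_dir))
    return reports


def _export_plots(intakes, ref, plot_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    n = len(ref["energy"])
    order = np.argsort(ref["energy"])
    xs = np.arange(n)
    width = 0.8 / (1 + len(intakes))

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(xs, ref["energy"][order], width, label="reference", color="tab:green")
    for j, (m, qs) in enumerate(sorted(intakes.items()), start=1):
        colour = {"system": "tab:blue", "scp": "tab:red"}.get(m)
        ax.bar(xs + j * width, qs["energy"][order], width, label=m, color=colour)
    ax.set_xlabel("meal (ordered by reference energy)")
    ax.set_ylabel("energy intake (kcal)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(plot_dir / "energy_bars.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    diffs = [qs["energy"] - ref["energy"] for _, qs in sorted(intakes.items())]
    ax.boxplot(diffs, tick_labels=sorted(intakes))
    ax.axhline(0.0, ls=":", color="k")
    ax.set_ylabel("estimated - reference energy (kcal)")
    fig.tight_layout()
    fig.savefig(plot_dir / "energy_differences_box.png", dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# simulation of meal sets (for harness sanity checks)


def simulate_meal_sets(
    rng: np.random.Generator,
    n_sets: int = 20,
    n_meals: int = 20,
    n_raters: int = 3,
    rater_sd: float = 0.05,
    system_sd: float = 0.03,
    scp_sd: float = 0.10,
) -> list[tuple[EstimateTable, MenuDatabase, dict]]:
    """Synthetic meal sets mirroring the study design.

    Per meal: 2-5 components with distinct nutrient profiles and independent
    true consumed fractions; raters observe each component's fraction with
    noise on coarse grids (their mean is the reference); the system observes
    per-component fractions with smaller noise; the SCP rounds a noisy
    whole-meal mean fraction to the 10% scale.
    """
    from .synthetic_scene import _random_nutrients
    import datetime as _dt

    from .menu_db import DishComponent, Menu, MenuDatabase, NutrientVector

    out = []
    for s in range(n_sets):
        rows = []
        db = MenuDatabase()
        sizes = {}
        for i in range(n_meals):
            meal_id = f"set{s}_meal{i}"
            date = _dt.date(2021, 1, 4) + _dt.timedelta(days=i)
            cats = list(
                rng.choice(
                    ["soup", "meat_fish", "side_dish", "vegetables_salad", "dessert"],
                    size=rng.integers(2, 6),
                    replace=False,
                )
            )
            comps = tuple(
                DishComponent(
                    f"sim {c}", c, 1.0, "portions",
                    NutrientVector(*(_random_nutrients(rng, c).values())),
                )
                for c in cats
            )
            db.add(Menu(date, "A", comps))
            size = rng.choice(list(MEAL_SIZES))
            sizes[meal_id] = (date, "A", size)

            true = {c: float(rng.uniform(0, 1)) for c in cats}
            for c in cats:
                for r in range(n_raters):
                    grid = 0.10 if r % 2 == 0 else 0.25
                    obs = np.clip(true[c] + rng.normal(0, rater_sd), 0, 1)
                    rows.append(
                        (meal_id, f"rater_{r + 1}", c, round(obs / grid) * grid)
                    )
                sys_obs = float(np.clip(true[c] + rng.normal(0, system_sd), 0, 1))
                rows.append((meal_id, "system", c, sys_obs))
            scp_obs = np.clip(np.mean(list(true.values())) + rng.normal(0, scp_sd), 0, 1)
            rows.append((meal_id, "scp", ALL, round(scp_obs / 0.10) * 0.10))
        table = EstimateTable(
            pd.DataFrame(rows, columns=["meal_id", "method", "category", "fraction"])
        )
        out.append((table, db, sizes))
    return out
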