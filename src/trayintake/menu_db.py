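"""Kitchen menu database: per-component nutrients and meal-size scaling.

A hospital kitchen serves, for each calendar date, a small set of menu
variants (e.g. A/B/C).  Each menu is composed of at most one dish per food
category (soup, meat/fish, side dish, sauce, vegetables/salad, dessert).
The database stores, per component, the quantity and the energy and
macronutrient content of a *normal-sized* serving; patients choose one of
four meal sizes and the stored values are scaled by the exact rational size
factor at lookup time.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import pandas as pd

__all__ = [
    "FOOD_CATEGORIES",
    "NutrientVector",
    "DishComponent",
    "MealSize",
    "MEAL_SIZES",
    "Menu",
    "MenuDatabase",
    "MenuSchemaError",
    "load_menu_db",
    "write_menu_db",
    "scale_nutrients",
    "lookup_scaled_meal",
]

#: The six food categories, in mask-label order (labels 1..6 of the food head).
FOOD_CATEGORIES: tuple[str, ...] = (
    "soup",
    "meat_fish",
    "side_dish",
    "sauce",
    "vegetables_salad",
    "dessert",
)

QUANTITY_UNITS = ("litres", "kilograms", "pieces", "portions")


class MenuSchemaError(ValueError):
    """Raised when a menu file violates the menu schema."""


@dataclass(frozen=True)
class NutrientVector:
    """Energy (kcal) and macronutrients (g) of one dish at one serving size.

    ``fatty_acids`` is the fatty-acid fraction of ``fat`` and can therefore
    never exceed it.
    """

    energy: float = 0.0
    cho: float = 0.0
    protein: float = 0.0
    fat: float = 0.0
    fatty_acids: float = 0.0

    def __post_init__(self) -> None:
        for name in ("energy", "cho", "protein", "fat", "fatty_acids"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValueError(f"nutrient {name!r} must be >= 0, got {v}")
        if self.fatty_acids > self.fat + 1e-9:
            raise ValueError(
                f"fatty_acids ({self.fatty_acids} g) exceeds total fat ({self.fat} g)"
            )

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(
            self.energy + other.energy,
            self.cho + other.cho,
            self.protein + other.protein,
            self.fat + other.fat,
            self.fatty_acids + other.fatty_acids,
        )

    def scaled(self, factor: float) -> "NutrientVector":
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return NutrientVector(
            self.energy * factor,
            self.cho * factor,
            self.protein * factor,
            self.fat * factor,
            self.fatty_acids * factor,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "energy": self.energy,
            "cho": self.cho,
            "protein": self.protein,
            "fat": self.fat,
            "fatty_acids": self.fatty_acids,
        }


@dataclass(frozen=True)
class DishComponent:
    name: str
    category: str
    quantity: float
    unit: str
    nutrients: NutrientVector

    def __post_init__(self) -> None:
        if self.category not in FOOD_CATEGORIES:
            raise MenuSchemaError(
                f"component {self.name!r}: unknown category {self.category!r}"
            )
        if not (self.quantity > 0):
            raise MenuSchemaError(
                f"component {self.name!r}: quantity must be > 0, got {self.quantity}"
            )
        if self.unit not in QUANTITY_UNITS:
            raise MenuSchemaError(
                f"component {self.name!r}: unknown unit {self.unit!r}"
            )


@dataclass(frozen=True)
class MealSize:
    """One of the four prescribable meal sizes with its exact size factor."""

    label: str
    factor: Fraction

    _TABLE = {
        "normal": Fraction(1),
        "increased": Fraction(4, 3),
        "reduced": Fraction(2, 3),
        "doubly_reduced": Fraction(1, 3),
    }

    def __post_init__(self) -> None:
        expected = self._TABLE.get(self.label)
        if expected is None:
            raise ValueError(f"unknown meal size label {self.label!r}")
        if self.factor != expected:
            raise ValueError(
                f"meal size {self.label!r} must have factor {expected}, got {self.factor}"
            )

    @classmethod
    def from_label(cls, label: str) -> "MealSize":
        if label not in cls._TABLE:
            raise ValueError(f"unknown meal size label {label!r}")
        return cls(label, cls._TABLE[label])


#: The four meal sizes keyed by label.
MEAL_SIZES: dict[str, MealSize] = {
    label: MealSize.from_label(label) for label in MealSize._TABLE
}


@dataclass(frozen=True)
class Menu:
    date: _dt.date
    variant: str
    components: tuple[DishComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise MenuSchemaError(
                f"menu ({self.date}, {self.variant!r}) has an empty component list"
            )
        cats = [c.category for c in self.components]
        dupes = {c for c in cats if cats.count(c) > 1}
        if dupes:
            raise MenuSchemaError(
                f"menu ({self.date}, {self.variant!r}) has more than one component "
                f"for categories {sorted(dupes)}"
            )

    @property
    def categories(self) -> set[str]:
        return {c.category for c in self.components}

    def component(self, category: str) -> DishComponent:
        for c in self.components:
            if c.category == category:
                return c
        raise KeyError(f"menu ({self.date}, {self.variant!r}) has no {category!r}")


@dataclass
class MenuDatabase:
    """Mapping (date, variant) -> :class:`Menu` with explicit-failure lookups."""

    menus: dict[tuple[_dt.date, str], Menu] = field(default_factory=dict)

    def add(self, menu: Menu) -> None:
        key = (menu.date, menu.variant)
        if key in self.menus:
            raise MenuSchemaError(f"duplicate menu key {key}")
        self.menus[key] = menu

    def lookup(self, date: _dt.date | str, variant: str) -> Menu:
        date = _coerce_date(date)
        try:
            return self.menus[(date, variant)]
        except KeyError:
            raise KeyError(
                f"no menu for date {date.isoformat()} variant {variant!r}"
            ) from None

    def __len__(self) -> int:
        return len(self.menus)

    def __iter__(self):
        return iter(self.menus.values())


def _coerce_date(date: _dt.date | str) -> _dt.date:
    if isinstance(date, _dt.date):
        return date
    return _dt.date.fromisoformat(str(date))


_COLUMNS = [
    "date",
    "variant",
    "category",
    "name",
    "quantity",
    "unit",
    "energy_kcal",
    "cho_g",
    "protein_g",
    "fat_g",
    "fatty_acids_g",
]


def load_menu_db(path: str | Path) -> MenuDatabase:
    """Load a menu database from a CSV file (one row per dish component).

    Columns: ``date`` (ISO-8601), ``variant``, ``category``, ``name``,
    ``quantity``, ``unit``, ``energy_kcal``, ``cho_g``, ``protein_g``,
    ``fat_g``, ``fatty_acids_g``.  Nutrients are per *normal-sized* serving.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"menu database file not found: {path}")
    df = pd.read_csv(path, dtype={"variant": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise MenuSchemaError(f"menu file {path} is missing columns {missing}")

    db = MenuDatabase()
    for (date_s, variant), grp in df.groupby(["date", "variant"], sort=True):
        components = []
        for _, row in grp.iterrows():
            try:
                nv = NutrientVector(
                    float(row["energy_kcal"]),
                    float(row["cho_g"]),
                    float(row["protein_g"]),
                    float(row["fat_g"]),
                    float(row["fatty_acids_g"]),
                )
            except ValueError as exc:
                raise MenuSchemaError(
                    f"menu ({date_s}, {variant!r}) component {row['name']!r}: {exc}"
                ) from exc
            components.append(
                DishComponent(
                    name=str(row["name"]),
                    category=str(row["category"]),
                    quantity=float(row["quantity"]),
                    unit=str(row["unit"]),
                    nutrients=nv,
                )
            )
        db.add(Menu(_coerce_date(str(date_s)), str(variant), tuple(components)))
    if not len(db):
        raise MenuSchemaError(f"menu file {path} contains no menus")
    return db


def write_menu_db(db: MenuDatabase, path: str | Path) -> None:
    """Write a menu database back to the CSV schema of :func:`load_menu_db`."""
    rows = []
    for menu in sorted(db, key=lambda m: (m.date, m.variant)):
        for c in menu.components:
            rows.append(
                {
                    "date": menu.date.isoformat(),
                    "variant": menu.variant,
                    "category": c.category,
                    "name": c.name,
                    "quantity": c.quantity,
                    "unit": c.unit,
                    "energy_kcal": c.nutrients.energy,
                    "cho_g": c.nutrients.cho,
                    "protein_g": c.nutrients.protein,
                    "fat_g": c.nutrients.fat,
                    "fatty_acids_g": c.nutrients.fatty_acids,
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def scale_nutrients(nv: NutrientVector, size: MealSize) -> NutrientVector:
    """Scale a normal-serving nutrient vector by the meal-size factor.

    The factor is applied as an exact rational so normal-size lookups
    round-trip bit-identically.
    """
    f = size.factor
    if f == 1:
        return nv
    return NutrientVector(
        self_mul(nv.energy, f),
        self_mul(nv.cho, f),
        self_mul(nv.protein, f),
        self_mul(nv.fat, f),
        self_mul(nv.fatty_acids, f),
    )


def self_mul(value: float, f: Fraction) -> float:
    return value * f.numerator / f.denominator


def lookup_scaled_meal(
    db: MenuDatabase,
    date: _dt.date | str,
    variant: str,
    size: MealSize,
) -> dict[str, NutrientVector]:
    """Return one size-scaled nutrient vector per category of the chosen menu."""
    menu = db.lookup(date, variant)
    return {c.category: scale_nutrients(c.nutrients, size) for c in menu.components}
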