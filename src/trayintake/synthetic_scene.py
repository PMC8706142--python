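"""Synthetic overhead RGB-D tray scenes with analytic ground truth.

The generator emulates the acquisition geometry of a standardised hospital
meal tray photographed from a fixed overhead mount (camera 47 cm above the
tray, 640x480 registered RGB + depth).  Scenes are built from parametric
solids — foods as cylinders, boxes, spherical caps (domes) and cone frusta,
containers as the four standardised vessels (round plate, soup bowl, square
bowl, glass) — so every placed item has a closed-form volume and the
rendered masks and depths have exact analytic references.

Rendering is an exact per-pixel ray cast under the full pinhole model (no
orthographic shortcut): each solid contributes an analytic ray-intersection
depth, the nearest hit wins, and class labels follow the fixed label tables.
Sensor imperfections (Gaussian depth noise, depth dropout — elevated over
liquid surfaces to mimic reflective soup) are applied *after* the ground
truth is extracted.

Paired before/after frames encode consumption by rescaling each food so the
remaining analytic volume equals ``(1 - fraction)`` times the original.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .labels import CONTAINER_TYPES, FOOD_LABELS, PLATE_LABELS
from .menu_db import FOOD_CATEGORIES, MenuDatabase, write_menu_db
from dataclasses import replace as _dc_replace

from .rgbd_io import DEFAULT_INTRINSICS, CameraIntrinsics, RGBDFrame, write_frame

#: Synthetic frames store depth in 0.25 mm counts: ideal parametric surfaces
#: are perfectly smooth, so millimetre rounding would alias flat tops onto a
#: few discrete levels instead of dithering out as it does on real food.
SYNTHETIC_INTRINSICS = _dc_replace(DEFAULT_INTRINSICS, depth_unit=0.00025)

__all__ = [
    "SolidSpec",
    "SceneSpec",
    "GroundTruth",
    "PairGroundTruth",
    "CONTAINER_GEOMETRY",
    "analytic_volume",
    "render_scene",
    "make_before_after_pair",
    "generate_dataset",
    "random_scene",
    "sample_fractions",
    "strip_foods",
    "SYNTHETIC_INTRINSICS",
    "fill_spec_for_bowl",
    "fill_spec_for_glass",
    "read_mask",
    "MEAL_SIZE_COUNTS",
    "COLOUR_STYLES",
]

FOOD_SHAPES = ("spherical_cap", "cylinder", "box", "cone_frustum")

#: Standardised container geometry (metres).  Containers on a hospital tray
#: are fixed crockery, so their cavity parameters are treated as calibratable
#: constants; :mod:`trayintake.volume_intake` uses the same registry as its
#: surface-model prior.
CONTAINER_GEOMETRY: dict[str, dict[str, float]] = {
    "round_plate": {"radius": 0.105, "height": 0.012},
    "soup_bowl": {
        "radius": 0.065,
        "height": 0.045,
        "cavity_radius": 0.055,
        "cavity_depth": 0.030,
    },
    "square_bowl": {"size_x": 0.100, "size_y": 0.100, "height": 0.030},
    "glass": {
        "radius": 0.035,
        "height": 0.070,
        "cavity_radius": 0.030,
        "cavity_depth": 0.050,
    },
}

#: Flat-colour tables (two "styles" emulating two hospital kitchens; style B
#: exists for cross-style pretraining experiments).
COLOUR_STYLES: dict[str, dict[str, tuple[int, int, int]]] = {
    "A": {
        "background": (70, 70, 75),
        "round_plate": (235, 235, 230),
        "soup_bowl": (220, 224, 228),
        "square_bowl": (226, 220, 210),
        "glass": (198, 208, 220),
        "soup": (196, 150, 60),
        "meat_fish": (150, 84, 50),
        "side_dish": (230, 200, 120),
        "sauce": (160, 40, 30),
        "vegetables_salad": (70, 140, 60),
        "dessert": (240, 180, 200),
    },
    "B": {
        "background": (96, 88, 70),
        "round_plate": (210, 214, 222),
        "soup_bowl": (238, 232, 214),
        "square_bowl": (205, 200, 225),
        "glass": (220, 215, 195),
        "soup": (120, 160, 70),
        "meat_fish": (120, 60, 80),
        "side_dish": (245, 225, 170),
        "sauce": (110, 70, 30),
        "vegetables_salad": (40, 110, 90),
        "dessert": (250, 215, 150),
    },
}


@dataclass(frozen=True)
class SolidSpec:
    """One parametric solid: a food item or a container.

    ``dims`` (metres) by shape: cylinder ``{radius, height}``; box
    ``{size_x, size_y, height}``; spherical_cap ``{base_radius, height}``;
    cone_frustum ``{radius_bottom, radius_top, height}``.  Container solids
    additionally carry ``cavity_radius`` / ``cavity_depth`` where concave.
    ``centre`` is (x, y) in tray-plane coordinates.
    """

    shape: str
    dims: dict
    centre: tuple[float, float]
    category: str
    colour: "tuple[int, int, int] | None" = None

    def __post_init__(self) -> None:
        if self.shape not in FOOD_SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        for k, v in self.dims.items():
            if not (v > 0):
                raise ValueError(f"{self.category}: dimension {k!r} must be > 0, got {v}")
        if self.category not in FOOD_CATEGORIES and self.category not in CONTAINER_TYPES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def is_container(self) -> bool:
        return self.category in CONTAINER_TYPES


@dataclass
class SceneSpec:
    """Full description of one tray scene."""

    containers: list[SolidSpec]
    foods: list[SolidSpec]
    camera_height: float = 0.47
    intrinsics: CameraIntrinsics = SYNTHETIC_INTRINSICS
    tray_z_offset: float = 0.0
    noise_sigma_mm: float = 0.0
    dropout: float = 0.0
    liquid_dropout: float = 0.0
    rgb_noise_sigma: float = 3.0
    colour_style: str = "A"
    seed: int = 0

    @property
    def tray_z(self) -> float:
        return self.camera_height + self.tray_z_offset


@dataclass
class GroundTruth:
    """Analytic ground truth extracted before any sensor noise is applied."""

    food_mask: np.ndarray
    plate_mask: np.ndarray
    volumes_ml: dict[str, float]
    clean_depth_m: np.ndarray
    in_frustum: dict[str, bool]
    fractions: dict[str, float] = field(default_factory=dict)


@dataclass
class PairGroundTruth:
    before: GroundTruth
    after: GroundTruth
    fractions: dict[str, float]
    volumes_before_ml: dict[str, float]
    volumes_after_ml: dict[str, float]


# --------------------------------------------------------------------------
# analytic volumes


def analytic_volume(s: SolidSpec) -> float:
    """Closed-form volume of a solid in millilitres."""
    d = s.dims
    if s.shape == "cylinder":
        v = np.pi * d["radius"] ** 2 * d["height"]
    elif s.shape == "box":
        v = d["size_x"] * d["size_y"] * d["height"]
    elif s.shape == "spherical_cap":
        a, h = d["base_radius"], d["height"]
        v = np.pi * h * (3 * a**2 + h**2) / 6.0
    elif s.shape == "cone_frustum":
        r1, r2, h = d["radius_bottom"], d["radius_top"], d["height"]
        v = np.pi * h * (r1**2 + r1 * r2 + r2**2) / 3.0
    else:  # pragma: no cover - guarded by SolidSpec
        raise ValueError(f"unknown shape {s.shape!r}")
    return float(v * 1e6)


def _cap_sphere_radius(base_radius: float, depth: float) -> float:
    return (base_radius**2 + depth**2) / (2.0 * depth)


# --------------------------------------------------------------------------
# exact ray-solid intersections (rays x = a z, y = b z, z > 0)

_EPS = 1e-12


def _circle_interval(a, b, x0, y0, r):
    """z-interval [t1, t2] during which the ray's lateral point lies inside
    the circle of radius r centred at (x0, y0); empty -> t1 > t2."""
    A = a * a + b * b
    B = -2.0 * (a * x0 + b * y0)
    C = x0 * x0 + y0 * y0 - r * r
    t1 = np.full(a.shape, np.inf)
    t2 = np.full(a.shape, -np.inf)
    quad = A > _EPS
    disc = B * B - 4.0 * A * C
    ok = quad & (disc >= 0.0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(ok, (-B - sq) / (2.0 * A), t1)
        t2 = np.where(ok, (-B + sq) / (2.0 * A), t2)
    central = ~quad
    inside = central & (C < 0.0)
    t1 = np.where(inside, 0.0, t1)
    t2 = np.where(inside, np.inf, t2)
    return t1, t2


def _hit_cylinder(a, b, x0, y0, r, z_top, z_base):
    t1, t2 = _circle_interval(a, b, x0, y0, r)
    lo = np.maximum(t1, z_top)
    hi = np.minimum(t2, z_base)
    return np.where((lo <= hi) & (lo > 0.0), lo, np.inf)


def _slab_interval(a, lo_v, hi_v):
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = a > _EPS
        neg = a < -_EPS
        t_lo = np.where(pos, lo_v / a, np.where(neg, hi_v / a, -np.inf))
        t_hi = np.where(pos, hi_v / a, np.where(neg, lo_v / a, np.inf))
    central = ~(pos | neg)
    outside = central & ~((lo_v <= 0.0) & (0.0 <= hi_v))
    t_lo = np.where(outside, np.inf, t_lo)
    t_hi = np.where(outside, -np.inf, t_hi)
    return t_lo, t_hi


def _hit_box(a, b, x1, x2, y1, y2, z_top, z_base):
    lx, hx = _slab_interval(a, x1, x2)
    ly, hy = _slab_interval(b, y1, y2)
    lo = np.maximum(np.maximum(lx, ly), z_top)
    hi = np.minimum(np.minimum(hx, hy), z_base)
    return np.where((lo <= hi) & (lo > 0.0), lo, np.inf)


def _sphere_roots(a, b, x0, y0, z0, R):
    A = a * a + b * b + 1.0
    B = -2.0 * (a * x0 + b * y0 + z0)
    C = x0 * x0 + y0 * y0 + z0 * z0 - R * R
    disc = B * B - 4.0 * A * C
    ok = disc >= 0.0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    z_near = np.where(ok, (-B - sq) / (2.0 * A), np.inf)
    z_far = np.where(ok, (-B + sq) / (2.0 * A), np.inf)
    return z_near, z_far


def _hit_dome(a, b, x0, y0, base_radius, height, z_base):
    """Spherical cap (dome) with its flat base on the plane z = z_base."""
    R = _cap_sphere_radius(base_radius, height)
    z_sc = z_base - height + R
    z_near, _ = _sphere_roots(a, b, x0, y0, z_sc, R)
    lat = np.hypot(a * z_near - x0, b * z_near - y0)
    valid = (
        np.isfinite(z_near)
        & (z_near > 0.0)
        & (z_near <= z_base + 1e-12)
        & (z_near >= z_base - height - 1e-12)
        & (lat <= base_radius * (1.0 + 1e-9))
    )
    return np.where(valid, z_near, np.inf)


def _hit_frustum(a, b, x0, y0, r_top, r_bottom, z_top, z_base):
    """Cone frustum, top radius at z_top, bottom radius at z_base."""
    # top disk
    lat_top = np.hypot(a * z_top - x0, b * z_top - y0)
    z_hit = np.where(lat_top <= r_top, z_top, np.inf)
    # lateral cone surface: radius(z) = c0 + s z
    s = (r_bottom - r_top) / (z_base - z_top)
    c0 = r_top - s * z_top
    A = a * a + b * b - s * s
    B = -2.0 * (a * x0 + b * y0) - 2.0 * c0 * s
    C = x0 * x0 + y0 * y0 - c0 * c0
    disc = B * B - 4.0 * A * C
    quad = np.abs(A) > _EPS
    ok = quad & (disc >= 0.0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(ok, (-B - sq) / (2.0 * A), np.inf)
        r2 = np.where(ok, (-B + sq) / (2.0 * A), np.inf)
        lin = ~quad & (np.abs(B) > _EPS)
        rl = np.where(lin, -C / np.where(lin, B, 1.0), np.inf)
    cand = np.stack([r1, r2, rl])
    in_range = (cand > z_top + 1e-12) & (cand <= z_base + 1e-12)
    cand = np.where(in_range, cand, np.inf)
    z_side = cand.min(axis=0)
    return np.minimum(z_hit, z_side)


def _hit_disk(a, b, x0, y0, r, z_disk):
    lat = np.hypot(a * z_disk - x0, b * z_disk - y0)
    return np.where(lat <= r, z_disk, np.inf)


# --------------------------------------------------------------------------
# scene assembly


def _container_for_food(food: SolidSpec, containers: list[SolidSpec]) -> SolidSpec:
    """A food belongs to the unique container whose footprint contains its centre."""
    fx, fy = food.centre
    owners = []
    for c in containers:
        cx, cy = c.centre
        if c.category == "square_bowl":
            inside = (
                abs(fx - cx) <= c.dims["size_x"] / 2
                and abs(fy - cy) <= c.dims["size_y"] / 2
            )
        else:
            inside = np.hypot(fx - cx, fy - cy) <= c.dims["radius"]
        if inside:
            owners.append(c)
    if len(owners) != 1:
        raise ValueError(
            f"food {food.category!r} at {food.centre} must lie in exactly one "
            f"container footprint (found {len(owners)})"
        )
    return owners[0]


def _check_container_overlap(containers: list[SolidSpec]) -> None:
    def extent(c):
        if c.category == "square_bowl":
            return max(c.dims["size_x"], c.dims["size_y"]) / 2 * np.sqrt(2)
        return c.dims["radius"]

    for i, c1 in enumerate(containers):
        for c2 in containers[i + 1 :]:
            d = np.hypot(c1.centre[0] - c2.centre[0], c1.centre[1] - c2.centre[1])
            if d < extent(c1) + extent(c2):
                raise ValueError(
                    f"containers {c1.category!r} and {c2.category!r} overlap"
                )


def _container_hit(c: SolidSpec, a, b, z_tray):
    x0, y0 = c.centre
    h = c.dims["height"]
    z_rim = z_tray - h
    if c.category == "round_plate":
        return _hit_cylinder(a, b, x0, y0, c.dims["radius"], z_rim, z_tray)
    if c.category == "square_bowl":
        sx, sy = c.dims["size_x"], c.dims["size_y"]
        return _hit_box(a, b, x0 - sx / 2, x0 + sx / 2, y0 - sy / 2, y0 + sy / 2, z_rim, z_tray)
    if c.category == "soup_bowl":
        ac, d = c.dims["cavity_radius"], c.dims["cavity_depth"]
        z_cyl = _hit_cylinder(a, b, x0, y0, c.dims["radius"], z_rim, z_tray)
        lat_rim = np.hypot(a * z_rim - x0, b * z_rim - y0)
        opening = np.isclose(z_cyl, z_rim) & (lat_rim < ac)
        R = _cap_sphere_radius(ac, d)
        z_sc = z_tray - (h - d) - R
        _, z_far = _sphere_roots(a, b, x0, y0, z_sc, R)
        z_cav = np.clip(z_far, z_rim, z_tray - (h - d) + 1e-12)
        z_cav = np.where(np.isfinite(z_far), z_cav, z_rim)
        return np.where(opening, z_cav, z_cyl)
    if c.category == "glass":
        ri, di = c.dims["cavity_radius"], c.dims["cavity_depth"]
        z_cbot = z_tray - (h - di)
        z_cyl = _hit_cylinder(a, b, x0, y0, c.dims["radius"], z_rim, z_tray)
        lat_rim = np.hypot(a * z_rim - x0, b * z_rim - y0)
        opening = np.isclose(z_cyl, z_rim) & (lat_rim < ri)
        _, t2i = _circle_interval(a, b, x0, y0, ri)
        z_in = np.where(t2i >= z_cbot, z_cbot, t2i)
        return np.where(opening, z_in, z_cyl)
    raise ValueError(f"unknown container type {c.category!r}")


def _food_hit(food: SolidSpec, container: SolidSpec, a, b, z_tray):
    """Ray-intersection depths of a food given its supporting container.

    On flat containers the solid sits on the container's top plane; in
    concave containers (soup bowl, glass) the food is a level fill whose
    visible surface is a horizontal disk at the fill level.
    """
    x0, y0 = food.centre
    ch = container.dims["height"]
    if container.category in ("round_plate", "square_bowl"):
        z_base = z_tray - ch
        h = food.dims["height"]
        if food.shape == "cylinder":
            return _hit_cylinder(a, b, x0, y0, food.dims["radius"], z_base - h, z_base)
        if food.shape == "box":
            sx, sy = food.dims["size_x"], food.dims["size_y"]
            return _hit_box(
                a, b, x0 - sx / 2, x0 + sx / 2, y0 - sy / 2, y0 + sy / 2, z_base - h, z_base
            )
        if food.shape == "spherical_cap":
            return _hit_dome(a, b, x0, y0, food.dims["base_radius"], h, z_base)
        if food.shape == "cone_frustum":
            return _hit_frustum(
                a, b, x0, y0, food.dims["radius_top"], food.dims["radius_bottom"],
                z_base - h, z_base,
            )
    elif container.category == "soup_bowl":
        if food.shape != "spherical_cap":
            raise ValueError("food in a soup bowl must be a spherical-cap level fill")
        d = container.dims["cavity_depth"]
        h = food.dims["height"]
        if h > d + 1e-9:
            raise ValueError("fill height exceeds bowl cavity depth")
        z_level = z_tray - (ch - d) - h
        return _hit_disk(a, b, *container.centre, food.dims["base_radius"], z_level)
    elif container.category == "glass":
        if food.shape != "cylinder":
            raise ValueError("food in a glass must be a cylindrical level fill")
        di = container.dims["cavity_depth"]
        h = food.dims["height"]
        if h > di + 1e-9:
            raise ValueError("fill height exceeds glass cavity depth")
        z_level = z_tray - (ch - di) - h
        return _hit_disk(a, b, *container.centre, food.dims["radius"], z_level)
    raise ValueError(
        f"shape {food.shape!r} not supported on container {container.category!r}"
    )


def fill_spec_for_bowl(
    container: SolidSpec, category: str, fill_height: float, colour=None
) -> SolidSpec:
    """Level fill of a soup bowl, expressed as the spherical cap it forms."""
    ac, d = container.dims["cavity_radius"], container.dims["cavity_depth"]
    if not (0 < fill_height <= d):
        raise ValueError("fill height must be in (0, cavity_depth]")
    R = _cap_sphere_radius(ac, d)
    base_radius = float(np.sqrt(fill_height * (2.0 * R - fill_height)))
    return SolidSpec(
        "spherical_cap",
        {"base_radius": base_radius, "height": fill_height},
        container.centre,
        category,
        colour,
    )


def fill_spec_for_glass(
    container: SolidSpec, category: str, fill_height: float, colour=None
) -> SolidSpec:
    """Level fill of a glass: a cylinder of the cavity bore."""
    if not (0 < fill_height <= container.dims["cavity_depth"]):
        raise ValueError("fill height must be in (0, cavity_depth]")
    return SolidSpec(
        "cylinder",
        {"radius": container.dims["cavity_radius"], "height": fill_height},
        container.centre,
        category,
        colour,
    )


def render_scene(spec: SceneSpec) -> tuple[RGBDFrame, GroundTruth]:
    """Exact z-buffer render of a scene: RGB-D frame plus analytic ground truth.

    Deterministic for a fixed ``spec.seed``; noise and dropout are applied to
    the depth map only after masks, clean depth and analytic volumes have
    been extracted.
    """
    _check_container_overlap(spec.containers)
    k = spec.intrinsics
    z_tray = spec.tray_z
    a, b = k.ray_slopes()

    depths = [np.full((k.height, k.width), z_tray)]  # item 0 = tray/background
    food_lab = [0]
    plate_lab = [0]
    colours = [COLOUR_STYLES[spec.colour_style]["background"]]
    liquid = [False]

    for c in spec.containers:
        depths.append(_container_hit(c, a, b, z_tray))
        food_lab.append(FOOD_LABELS["plate"])
        plate_lab.append(PLATE_LABELS[c.category])
        colours.append(c.colour or COLOUR_STYLES[spec.colour_style][c.category])
        liquid.append(False)

    in_frustum: dict[str, bool] = {}
    for f in spec.foods:
        cont = _container_for_food(f, spec.containers)
        hit = _food_hit(f, cont, a, b, z_tray)
        visible = np.isfinite(hit).any()
        in_frustum[f.category] = bool(visible)
        if not visible:
            warnings.warn(
                f"food {f.category!r} at {f.centre} falls outside the camera frustum",
                stacklevel=2,
            )
        depths.append(hit)
        food_lab.append(FOOD_LABELS[f.category])
        plate_lab.append(0)
        colours.append(f.colour or COLOUR_STYLES[spec.colour_style][f.category])
        liquid.append(cont.category in ("soup_bowl", "glass"))

    stack = np.stack(depths)
    winner = np.argmin(stack, axis=0)
    z = np.take_along_axis(stack, winner[None], axis=0)[0]

    food_mask = np.asarray(food_lab, dtype=np.uint8)[winner]
    plate_mask = np.asarray(plate_lab, dtype=np.uint8)[winner]
    liquid_mask = np.asarray(liquid)[winner]

    volumes = {}
    for f in spec.foods:
        volumes[f.category] = volumes.get(f.category, 0.0) + analytic_volume(f)

    gt = GroundTruth(
        food_mask=food_mask,
        plate_mask=plate_mask,
        volumes_ml=volumes,
        clean_depth_m=z.copy(),
        in_frustum=in_frustum,
    )

    rng = np.random.default_rng(spec.seed)
    z_noisy = z
    if spec.noise_sigma_mm > 0:
        z_noisy = z + rng.normal(0.0, spec.noise_sigma_mm * 1e-3, z.shape)
    counts = np.round(z_noisy / k.depth_unit).astype(np.int64)
    counts = np.clip(counts, 0, np.iinfo(np.uint16).max)
    p_drop = np.full(z.shape, spec.dropout)
    if spec.liquid_dropout > 0:
        p_drop = np.where(liquid_mask, spec.liquid_dropout, p_drop)
    if (p_drop > 0).any():
        counts[rng.uniform(size=z.shape) < p_drop] = 0
    depth16 = counts.astype(np.uint16)

    rgb = np.asarray(colours, dtype=np.float64)[winner]
    if spec.rgb_noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, spec.rgb_noise_sigma, rgb.shape)
    rgb8 = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    frame = RGBDFrame(rgb=rgb8, depth=depth16, meta={})
    return frame, gt


def strip_foods(spec: SceneSpec) -> SceneSpec:
    """The same scene with every food removed (containers only)."""
    return replace(spec, foods=[])


# --------------------------------------------------------------------------
# consumption


def _shrink_food(
    food: SolidSpec, container: SolidSpec, fraction: float
) -> "SolidSpec | None":
    """Rescale a food so its analytic volume becomes (1 - fraction) of itself."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if fraction == 0.0:
        return food
    if fraction == 1.0:
        return None
    keep = 1.0 - fraction
    d = dict(food.dims)
    if container.category == "soup_bowl":
        # level fill: solve the cap depth of the cavity sphere for the target volume
        R = _cap_sphere_radius(container.dims["cavity_radius"], container.dims["cavity_depth"])
        h0 = d["height"]
        target = keep * h0 * h0 * (3.0 * R - h0)  # proportional to cap volume
        h_new = brentq(lambda h: h * h * (3.0 * R - h) - target, 1e-9, h0)
        d["height"] = h_new
        d["base_radius"] = float(np.sqrt(h_new * (2.0 * R - h_new)))
    elif food.shape == "spherical_cap":
        # dome with fixed base radius: solve h (3a^2 + h^2) for the target volume
        aa, h0 = d["base_radius"], d["height"]
        target = keep * h0 * (3.0 * aa**2 + h0**2)
        h_new = brentq(lambda h: h * (3.0 * aa**2 + h**2) - target, 1e-9, h0)
        d["height"] = h_new
    else:
        # cylinder / box / frustum-with-fixed-radii / glass fill: volume linear in height
        d["height"] = d["height"] * keep
    return replace(food, dims=d)


def make_before_after_pair(
    spec: SceneSpec, fractions: dict[str, float]
) -> tuple[RGBDFrame, RGBDFrame, PairGroundTruth]:
    """Render a consumption pair: the before scene and the same scene with
    each food shrunk so its remaining analytic volume is ``(1 - fraction)``
    of the original (fraction 1 removes the item)."""
    present = {f.category for f in spec.foods}
    unknown = set(fractions) - present
    if unknown:
        raise ValueError(f"fractions given for categories not in scene: {sorted(unknown)}")

    before_frame, before_gt = render_scene(spec)

    after_foods = []
    for f in spec.foods:
        shrunk = _shrink_food(f, _container_for_food(f, spec.containers), fractions.get(f.category, 0.0))
        if shrunk is not None:
            after_foods.append(shrunk)
    after_spec = replace(spec, foods=after_foods, seed=spec.seed + 1)
    after_frame, after_gt = render_scene(after_spec)

    full = {cat: fractions.get(cat, 0.0) for cat in present}
    after_gt.fractions = full
    pair_gt = PairGroundTruth(
        before=before_gt,
        after=after_gt,
        fractions=full,
        volumes_before_ml=dict(before_gt.volumes_ml),
        volumes_after_ml={
            cat: after_gt.volumes_ml.get(cat, 0.0) for cat in present
        },
    )
    return before_frame, after_frame, pair_gt


# --------------------------------------------------------------------------
# random scenes and datasets


def _jitter(rng, xy, r=0.008):
    return (xy[0] + rng.uniform(-r, r), xy[1] + rng.uniform(-r, r))


def random_scene(
    rng: np.random.Generator,
    intrinsics: CameraIntrinsics = SYNTHETIC_INTRINSICS,
    style: str = "A",
    noise_sigma_mm: float = 0.0,
    dropout: float = 0.0,
    liquid_dropout: float = 0.0,
    categories: "set[str] | None" = None,
) -> SceneSpec:
    """Sample a typical tray: soup bowl, round plate with up to three
    components plus sauce, and a dessert vessel (square bowl or glass)."""
    if categories is None:
        categories = {"soup", "meat_fish", "side_dish", "vegetables_salad", "dessert"}
        if rng.uniform() < 0.5:
            categories.add("sauce")
    geo = CONTAINER_GEOMETRY

    bowl = SolidSpec("cylinder", dict(geo["soup_bowl"]), _jitter(rng, (-0.150, -0.085)), "soup_bowl")
    plate = SolidSpec("cylinder", dict(geo["round_plate"]), _jitter(rng, (0.095, 0.000)), "round_plate")
    containers = [bowl, plate]
    dessert_in_glass = rng.uniform() < 0.5
    if dessert_in_glass:
        dvessel = SolidSpec("cylinder", dict(geo["glass"]), _jitter(rng, (-0.150, 0.100)), "glass")
    else:
        dvessel = SolidSpec("box", dict(geo["square_bowl"]), _jitter(rng, (-0.155, 0.105)), "square_bowl")
    containers.append(dvessel)

    foods: list[SolidSpec] = []
    if "soup" in categories:
        foods.append(fill_spec_for_bowl(bowl, "soup", rng.uniform(0.012, 0.026)))
    px, py = plate.centre
    if "meat_fish" in categories:
        if rng.uniform() < 0.5:
            foods.append(SolidSpec(
                "spherical_cap",
                {"base_radius": rng.uniform(0.028, 0.036), "height": rng.uniform(0.012, 0.022)},
                (px - 0.045, py - 0.008), "meat_fish",
            ))
        else:
            foods.append(SolidSpec(
                "cylinder",
                {"radius": rng.uniform(0.024, 0.032), "height": rng.uniform(0.010, 0.020)},
                (px - 0.045, py - 0.008), "meat_fish",
            ))
    if "side_dish" in categories:
        foods.append(SolidSpec(
            "box",
            {"size_x": rng.uniform(0.040, 0.055), "size_y": rng.uniform(0.035, 0.050),
             "height": rng.uniform(0.012, 0.024)},
            (px + 0.042, py - 0.038), "side_dish",
        ))
    if "vegetables_salad" in categories:
        foods.append(SolidSpec(
            "cone_frustum",
            {"radius_bottom": rng.uniform(0.026, 0.034),
             "radius_top": rng.uniform(0.014, 0.022), "height": rng.uniform(0.012, 0.022)},
            (px + 0.040, py + 0.042), "vegetables_salad",
        ))
    if "sauce" in categories:
        foods.append(SolidSpec(
            "cylinder",
            {"radius": rng.uniform(0.016, 0.022), "height": rng.uniform(0.004, 0.008)},
            (px - 0.040, py + 0.048), "sauce",
        ))
    if "dessert" in categories:
        if dessert_in_glass:
            foods.append(fill_spec_for_glass(dvessel, "dessert", rng.uniform(0.018, 0.040)))
        else:
            foods.append(SolidSpec(
                "spherical_cap",
                {"base_radius": rng.uniform(0.024, 0.034), "height": rng.uniform(0.010, 0.020)},
                dvessel.centre, "dessert",
            ))

    return SceneSpec(
        containers=containers,
        foods=foods,
        intrinsics=intrinsics,
        noise_sigma_mm=noise_sigma_mm,
        dropout=dropout,
        liquid_dropout=liquid_dropout,
        colour_style=style,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


#: Empirical meal-size distribution of the study population (counts of
#: normal / increased / reduced / doubly reduced meals among 166 recorded).
MEAL_SIZE_COUNTS: dict[str, int] = {
    "normal": 51,
    "increased": 6,
    "reduced": 85,
    "doubly_reduced": 24,
}

_NUTRIENT_RANGES = {
    # per normal serving: (energy kcal, cho g, protein g, fat g) ranges
    "soup": ((90, 220), (8, 22), (4, 14), (2, 8)),
    "meat_fish": ((120, 280), (0, 6), (15, 32), (4, 16)),
    "side_dish": ((120, 300), (20, 55), (3, 9), (1, 8)),
    "sauce": ((30, 90), (2, 8), (0.5, 3), (2, 7)),
    "vegetables_salad": ((25, 90), (4, 12), (1, 4), (0.5, 5)),
    "dessert": ((90, 250), (14, 35), (3, 12), (2, 10)),
}


def _random_nutrients(rng: np.random.Generator, category: str):
    (e, c, p, f) = _NUTRIENT_RANGES[category]
    fat = rng.uniform(*f)
    return {
        "energy_kcal": round(rng.uniform(*e), 1),
        "cho_g": round(rng.uniform(*c), 1),
        "protein_g": round(rng.uniform(*p), 1),
        "fat_g": round(fat, 1),
        "fatty_acids_g": round(fat * rng.uniform(0.3, 0.7), 1),
    }


def sample_fractions(rng: np.random.Generator, categories) -> dict[str, float]:
    """Consumed fractions with realistic mass at "ate everything" / "ate nothing"."""
    out = {}
    for cat in categories:
        u = rng.uniform()
        if u < 0.20:
            out[cat] = 1.0
        elif u < 0.30:
            out[cat] = 0.0
        else:
            out[cat] = float(np.round(rng.uniform(0.05, 0.95), 3))
    return out


def generate_dataset(
    n_scenes: int,
    seed: int,
    out_dir: str | Path,
    intrinsics: CameraIntrinsics = SYNTHETIC_INTRINSICS,
    style: str = "A",
    noise_sigma_mm: float = 0.0,
    dropout: float = 0.0,
    liquid_dropout: float = 0.0,
) -> dict:
    """Write ``n_scenes`` before/after pairs with masks, ground truth and a
    matching menu database; fully reproducible from ``seed``.

    Layout per scene ``i``: ``scene_XXX/{before,after}_{rgb,depth}.png``,
    indexed-PNG masks, ``gt.json``; plus a top-level ``menu.csv`` and
    ``index.json``.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    import pandas as pd

    from .menu_db import Menu, DishComponent, NutrientVector, MenuDatabase

    size_labels = list(MEAL_SIZE_COUNTS)
    size_p = np.array(list(MEAL_SIZE_COUNTS.values()), dtype=float)
    size_p /= size_p.sum()

    db = MenuDatabase()
    index = []
    base_date = _dt.date(2021, 1, 4)
    for i in range(n_scenes):
        spec = random_scene(
            rng, intrinsics=intrinsics, style=style,
            noise_sigma_mm=noise_sigma_mm, dropout=dropout, liquid_dropout=liquid_dropout,
        )
        cats = [f.category for f in spec.foods]
        fractions = sample_fractions(rng, cats)
        before, after, pair_gt = make_before_after_pair(spec, fractions)

        date = base_date + _dt.timedelta(days=i)
        variant = "A"
        size = size_labels[rng.choice(len(size_labels), p=size_p)]
        meta = {
            "patient_id": f"p{i:03d}",
            "meal_variant": variant,
            "meal_size": size,
            "date": date.isoformat(),
            "timestamp": f"{date.isoformat()}T12:00:00",
        }
        comps = tuple(
            DishComponent(
                name=f"synthetic {cat}",
                category=cat,
                quantity=1.0,
                unit="portions",
                nutrients=NutrientVector(*(_random_nutrients(rng, cat).values())),
            )
            for cat in cats
        )
        db.add(Menu(date, variant, comps))

        sdir = out_dir / f"scene_{i:03d}"
        sdir.mkdir(exist_ok=True)
        for phase, frame, gt in (
            ("before", before, pair_gt.before),
            ("after", after, pair_gt.after),
        ):
            frame.meta = {**meta, "phase": phase}
            write_frame(frame, sdir / f"{phase}_rgb.png", sdir / f"{phase}_depth.png")
            _write_mask(gt.food_mask, sdir / f"{phase}_food_mask.png")
            _write_mask(gt.plate_mask, sdir / f"{phase}_plate_mask.png")
        (sdir / "gt.json").write_text(json.dumps({
            "fractions": pair_gt.fractions,
            "volumes_before_ml": pair_gt.volumes_before_ml,
            "volumes_after_ml": pair_gt.volumes_after_ml,
            "meal_size": size,
            "date": date.isoformat(),
            "variant": variant,
        }, indent=1))
        index.append({"scene": f"scene_{i:03d}", **meta})

    write_menu_db(db, out_dir / "menu.csv")
    (out_dir / "index.json").write_text(json.dumps(index, indent=1))
    return {"n_scenes": n_scenes, "out_dir": str(out_dir)}


def _write_mask(mask: np.ndarray, path: Path) -> None:
    from PIL import Image

    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = np.zeros((256, 3), dtype=np.uint8)
    # distinct palette entries for up to 8 labels
    base = np.array([
        [0, 0, 0], [60, 90, 200], [60, 170, 80], [230, 210, 90], [210, 60, 50],
        [230, 140, 190], [120, 210, 230], [240, 240, 240],
    ], dtype=np.uint8)
    palette[: len(base)] = base
    im.putpalette(palette.reshape(-1).tolist())
    im.save(path)


def read_mask(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path), dtype=np.uint8)
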