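"""Core volumetry: plate/food surface reconstruction, per-category volume,
consumed fractions, and energy/macronutrient intake.

The pipeline for one meal: back-project both depth maps to point clouds,
reconstruct the container ("plate") surface beneath each food from the
visible container pixels, integrate the vertical height between the food
surface and the plate surface over each food-category region, form consumed
fractions from the before/after volumes, and multiply each fraction by the
size-scaled nutrients of the matching menu component (sauce is excluded from
meal totals, mirroring the estimation protocol of the dietitians).

Volume integral
---------------
Writing ``(u, v)`` for tray-plane (lateral) coordinates, the volume of a
food is ``∫∫ h(u, v) du dv`` with ``h`` the vertical height of the food
surface above the reconstructed plate surface.  Each depth pixel is a sample
of the visible surface; changing variables from pixel coordinates to
``(u, v)`` gives the per-pixel lateral footprint ``|J| = (z + a z_a)(z + b
z_b) / (fx fy)`` where ``a, b`` are the pixel's ray slopes and ``z_a, z_b``
the depth-map derivatives along them.  This reduces to the familiar
``z²/(fx·fy)`` footprint on locally level surfaces and correctly compresses
the footprint of steep (side-wall) pixels, so the integral recovers the true
footprint even for vertical-walled items seen off-axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .labels import FOOD_LABELS, PLATE_LABELS
from .menu_db import MealSize, Menu, NutrientVector, scale_nutrients
from .rgbd_io import CameraIntrinsics, PointCloud, RGBDFrame, depth_to_cloud
from .synthetic_scene import CONTAINER_GEOMETRY, _cap_sphere_radius

__all__ = [
    "InvalidSurfaceError",
    "PlaneModel",
    "SphereModel",
    "OffsetPlaneModel",
    "SurfaceGrid",
    "CategoryVolume",
    "VolumeEstimate",
    "IntakeRecord",
    "reconstruct_plate_surface",
    "estimate_food_volume",
    "consumed_fraction",
    "compute_intake",
    "estimate_meal",
    "snap_fraction",
]

FLAT_CONTAINERS = ("round_plate", "square_bowl")


class InvalidSurfaceError(RuntimeError):
    """Raised when a container surface cannot be reconstructed at all."""


# --------------------------------------------------------------------------
# surface models


@dataclass(frozen=True)
class PlaneModel:
    """z = c0 + c1*u + c2*v (camera-frame depth as a function of lateral position)."""

    c0: float
    c1: float
    c2: float

    def z_vertical(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return self.c0 + self.c1 * u + self.c2 * v

    def z_along_rays(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        denom = 1.0 - self.c1 * a - self.c2 * b
        return self.c0 / denom


@dataclass(frozen=True)
class SphereModel:
    """Concave cavity surface: the lower (far-from-camera) sheet of a sphere."""

    cx: float
    cy: float
    cz: float
    radius: float

    def z_vertical(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        d2 = self.radius**2 - (u - self.cx) ** 2 - (v - self.cy) ** 2
        return self.cz + np.sqrt(np.clip(d2, 0.0, None))

    def z_along_rays(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        A = a * a + b * b + 1.0
        B = -2.0 * (a * self.cx + b * self.cy + self.cz)
        C = self.cx**2 + self.cy**2 + self.cz**2 - self.radius**2
        disc = np.clip(B * B - 4.0 * A * C, 0.0, None)
        return (-B + np.sqrt(disc)) / (2.0 * A)


@dataclass(frozen=True)
class OffsetPlaneModel:
    """A plane displaced vertically from a fitted rim plane (glass bottom).

    ``bore_radius`` carries the calibrated cavity cross-section so level
    fills can be integrated as height x bore area (the visible-surface
    footprint of a liquid in a narrow vessel is clipped by the near rim,
    so a footprint integral would be biased; the level is not).
    """

    rim: PlaneModel
    depth_offset: float  # metres below the rim (+z)
    bore_radius: float = float("nan")

    def z_vertical(self, u, v):
        return self.rim.z_vertical(u, v) + self.depth_offset

    def z_along_rays(self, a, b):
        shifted = PlaneModel(self.rim.c0 + self.depth_offset, self.rim.c1, self.rim.c2)
        return shifted.z_along_rays(a, b)


@dataclass
class SurfaceGrid:
    """Reconstructed container surface over a pixel support set."""

    model: "PlaneModel | SphereModel | OffsetPlaneModel"
    support: np.ndarray  # H x W bool: container + associated food pixels
    valid: bool
    plate_type: str
    method: str  # "plane_fit" | "sphere_fit" | "registry_prior" | ...
    n_fit_pixels: int = 0
    fit_rms_m: float = float("nan")

    def z_map(self, k: CameraIntrinsics) -> np.ndarray:
        """Surface depth along each pixel ray over the support (NaN outside)."""
        a, b = k.ray_slopes()
        z = np.asarray(self.model.z_along_rays(a, b), dtype=np.float64)
        out = np.full(self.support.shape, np.nan)
        out[self.support] = z[self.support]
        return out


def _fit_plane(points: np.ndarray, max_iter: int = 3) -> tuple[PlaneModel, int, float]:
    """Robust least-squares plane z = c0 + c1 x + c2 y with residual trimming."""
    pts = points
    keep = np.ones(len(pts), dtype=bool)
    coef = None
    for _ in range(max_iter):
        p = pts[keep]
        A = np.column_stack([np.ones(len(p)), p[:, 0], p[:, 1]])
        coef, *_ = np.linalg.lstsq(A, p[:, 2], rcond=None)
        resid = pts[:, 2] - (coef[0] + coef[1] * pts[:, 0] + coef[2] * pts[:, 1])
        mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
        tol = max(0.002, 3.0 * 1.4826 * mad)
        new_keep = np.abs(resid) <= tol
        if new_keep.sum() < 10 or new_keep.all():
            keep = new_keep if new_keep.sum() >= 10 else keep
            break
        keep = new_keep
    p = pts[keep]
    rms = float(np.sqrt(np.mean((p[:, 2] - (coef[0] + coef[1] * p[:, 0] + coef[2] * p[:, 1])) ** 2)))
    return PlaneModel(*map(float, coef)), int(keep.sum()), rms


def _fit_sphere(points: np.ndarray, max_iter: int = 3):
    """Algebraic least-squares sphere fit |p - c|^2 = R^2 with trimming."""
    pts = points
    keep = np.ones(len(pts), dtype=bool)
    centre, radius = None, None
    for _ in range(max_iter):
        p = pts[keep]
        A = np.column_stack([2.0 * p, np.ones(len(p))])
        bvec = (p**2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, bvec, rcond=None)
        centre = sol[:3]
        radius = float(np.sqrt(max(sol[3] + centre @ centre, 0.0)))
        resid = np.linalg.norm(pts - centre, axis=1) - radius
        mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
        tol = max(0.002, 3.0 * 1.4826 * mad)
        new_keep = np.abs(resid) <= tol
        if new_keep.sum() < 20 or new_keep.all():
            keep = new_keep if new_keep.sum() >= 20 else keep
            break
        keep = new_keep
    p = pts[keep]
    rms = float(np.sqrt(np.mean((np.linalg.norm(p - centre, axis=1) - radius) ** 2)))
    return centre, radius, int(keep.sum()), rms


def associate_food_pixels(plate_mask: np.ndarray, food_mask: np.ndarray) -> np.ndarray:
    """Assign every food pixel the plate-type label of its nearest container pixel."""
    has_plate = plate_mask > 0
    if not has_plate.any():
        return np.zeros_like(plate_mask)
    _, (ir, ic) = ndimage.distance_transform_edt(~has_plate, return_indices=True)
    owner = plate_mask[ir, ic]
    out = np.zeros_like(plate_mask)
    foodpix = (food_mask > 0) & (food_mask != FOOD_LABELS["plate"])
    out[foodpix] = owner[foodpix]
    return out


def reconstruct_plate_surface(
    cloud: PointCloud,
    plate_mask: np.ndarray,
    food_mask: np.ndarray,
    plate_type: str,
    k: CameraIntrinsics,
    container_registry: "dict | None" = None,
) -> SurfaceGrid:
    """Reconstruct the container surface (including beneath its food).

    Flat containers (round plate, square bowl) use a robust plane fit to the
    visible container pixels.  The soup bowl uses a spherical cavity model
    fitted to the visible interior pixels, falling back to the calibrated
    container registry (rim plane + nominal cavity sphere) when too little
    interior is visible.  The glass's cylindrical bore hides its bottom
    whenever dessert is present, so its bottom plane is the fitted rim plane
    displaced by the registry's cavity depth (or a direct plane fit when the
    bottom *is* visible).
    """
    if plate_type not in PLATE_LABELS or plate_type == "background":
        raise ValueError(f"unknown plate type {plate_type!r}")
    registry = container_registry if container_registry is not None else CONTAINER_GEOMETRY

    plate_region = plate_mask == PLATE_LABELS[plate_type]
    z = cloud.z_map()
    vis = plate_region & np.isfinite(z)
    if not vis.any():
        raise InvalidSurfaceError(
            f"container {plate_type!r}: no visible container pixels with valid depth"
        )
    owner = associate_food_pixels(plate_mask, food_mask)
    support = plate_region | (owner == PLATE_LABELS[plate_type])

    rows, cols = np.nonzero(vis)
    zv = z[rows, cols]
    a = (cols - k.cx) / k.fx
    b = (rows - k.cy) / k.fy
    pts = np.column_stack([a * zv, b * zv, zv])

    if plate_type in FLAT_CONTAINERS:
        model, n_fit, rms = _fit_plane(pts)
        return SurfaceGrid(model, support, True, plate_type, "plane_fit", n_fit, rms)

    # concave containers: split rim ring from cavity interior *geometrically*
    # (lateral annulus around the footprint centre, radii from the calibrated
    # registry).  A depth-percentile split would select the low-noise tail of
    # the rim under sensor noise and bias the rim plane shallow.
    geo = registry[plate_type]
    # centre from the shallowest (rim-top) pixels: a plain footprint centroid
    # would be dragged sideways by the tall outer flank of an off-axis vessel
    shallow = pts[pts[:, 2] <= np.percentile(pts[:, 2], 5) + 0.002]
    uc0, vc0 = float(np.median(shallow[:, 0])), float(np.median(shallow[:, 1]))
    lat = np.hypot(pts[:, 0] - uc0, pts[:, 1] - vc0)
    r_cav = geo["cavity_radius"]
    r_out = geo["radius"]
    band = pts[(lat > r_cav * 1.03) & (lat < r_out - 0.002)]
    # depth-gate the lateral band by an iterated median: wall and flank pixels
    # leak into the band (lateral noise) and sit several cm deeper than the rim
    rim_pts = band
    for _ in range(3):
        if not len(rim_pts):
            break
        z_med = np.median(rim_pts[:, 2])
        rim_pts = band[np.abs(band[:, 2] - z_med) <= 0.005]
    z_rim = np.median(rim_pts[:, 2]) if len(rim_pts) else np.percentile(pts[:, 2], 5)
    interior = pts[(lat < r_cav * 0.92) & (pts[:, 2] > z_rim + 0.004)]

    if plate_type == "soup_bowl":
        if len(interior) >= 50:
            centre, radius, n_fit, rms = _fit_sphere(interior)
            # a thin visible annulus (soup nearly to the rim) extrapolates the
            # bottom poorly even when residuals look small — depth quantisation
            # alone breaks it — so a deep visible span of the cavity is always
            # required for the fit to stand
            span = float(np.percentile(interior[:, 2], 95) - np.percentile(interior[:, 2], 5))
            if 0.04 <= radius <= 0.15 and rms < 0.0015 and span >= 0.6 * geo["cavity_depth"]:
                model = SphereModel(*map(float, centre), radius)
                return SurfaceGrid(model, support, True, plate_type, "sphere_fit", n_fit, rms)
        # fallback: nominal cavity sphere hung from the fitted rim plane
        R = _cap_sphere_radius(geo["cavity_radius"], geo["cavity_depth"])
        if len(rim_pts) < 10:
            raise InvalidSurfaceError("soup_bowl: neither interior nor rim visible")
        rim_plane, n_fit, rms = _fit_plane(rim_pts)
        uc, vc = float(np.mean(rim_pts[:, 0])), float(np.mean(rim_pts[:, 1]))
        cz = rim_plane.z_vertical(uc, vc) + geo["cavity_depth"] - R
        model = SphereModel(uc, vc, float(cz), R)
        return SurfaceGrid(model, support, True, plate_type, "registry_prior", n_fit, rms)

    # glass
    if len(interior) >= 50:
        # bottom visible (empty or nearly empty glass): fit it directly, but
        # only accept a near-level, genuinely planar fit (bore-wall slivers
        # masquerading as "interior" fail these gates)
        model, n_fit, rms = _fit_plane(interior)
        if rms < 0.002 and abs(model.c1) < 0.15 and abs(model.c2) < 0.15:
            return SurfaceGrid(model, support, True, plate_type, "bottom_plane_fit", n_fit, rms)
    if len(rim_pts) < 10:
        raise InvalidSurfaceError("glass: neither bottom nor rim visible")
    rim_plane, n_fit, rms = _fit_plane(rim_pts)
    model = OffsetPlaneModel(rim_plane, geo["cavity_depth"], geo["cavity_radius"])
    return SurfaceGrid(model, support, True, plate_type, "registry_prior", n_fit, rms)


# --------------------------------------------------------------------------
# volume integration


@dataclass
class CategoryVolume:
    """Volume estimate for one food category in one frame."""

    category: str
    volume_ml: float
    pixel_count: int
    missing_fraction: float = 0.0
    clamped_fraction: float = 0.0
    low_confidence: bool = False
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and self.volume_ml < 0:
            raise ValueError("volumes must be non-negative")


@dataclass
class VolumeEstimate:
    """Per-category volumes for one frame phase."""

    phase: str
    volumes: dict[str, CategoryVolume] = field(default_factory=dict)

    def volume_ml(self, category: str) -> float:
        return self.volumes[category].volume_ml


def _nan_gradient(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central differences falling back to one-sided at NaN boundaries."""

    def axis_grad(zz, axis):
        fwd = np.roll(zz, -1, axis=axis)
        bwd = np.roll(zz, 1, axis=axis)
        both = np.isfinite(fwd) & np.isfinite(bwd)
        f_only = np.isfinite(fwd) & ~np.isfinite(bwd)
        b_only = ~np.isfinite(fwd) & np.isfinite(bwd)
        g = np.zeros_like(zz)
        g = np.where(both, (fwd - bwd) / 2.0, g)
        g = np.where(f_only, fwd - zz, g)
        g = np.where(b_only, zz - bwd, g)
        return g

    return axis_grad(z, 0), axis_grad(z, 1)  # d/drow, d/dcol


def _smooth_in_mask(z: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Normalised Gaussian smoothing confined to the mask (NaN-safe)."""
    w = mask & np.isfinite(z)
    num = ndimage.gaussian_filter(np.where(w, z, 0.0), sigma)
    den = ndimage.gaussian_filter(w.astype(np.float64), sigma)
    out = np.where(den > 1e-9, num / np.maximum(den, 1e-9), np.nan)
    return np.where(mask, out, np.nan)


def estimate_food_volume(
    cloud: PointCloud,
    food_mask: np.ndarray,
    plate_surface: SurfaceGrid,
    category: str,
    k: CameraIntrinsics,
    gradient_smooth_sigma: float = 1.5,
) -> CategoryVolume:
    """Integrate the food-above-plate height field over one category region.

    Missing-depth pixels inside the region are filled from their nearest
    valid neighbour within the region; pixels with no neighbour are excluded
    and counted.  Negative columns (food below the reconstructed plate, from
    noise) are clamped to zero per pixel and reported as a clamped fraction.
    A region with more than half of its depth missing is flagged low
    confidence.
    """
    label = FOOD_LABELS[category]
    region = food_mask == label
    n_pix = int(region.sum())
    if n_pix == 0:
        raise ValueError(f"category {category!r} absent from food mask")
    if not plate_surface.valid:
        return CategoryVolume(category, 0.0, n_pix, valid=False)

    z = cloud.z_map()
    covered = plate_surface.support[region].mean()
    if covered < 0.99:
        warnings.warn(
            f"{category}: {100 * (1 - covered):.1f}% of region outside the "
            "reconstructed surface support",
            stacklevel=2,
        )

    valid = region & np.isfinite(z)
    missing = region & ~np.isfinite(z)
    missing_fraction = float(missing.sum() / n_pix)
    zf = np.where(region, z, np.nan)
    if missing.any() and valid.any():
        _, (ir, ic) = ndimage.distance_transform_edt(~valid, return_indices=True)
        fill = z[ir, ic]
        inside = region[ir, ic]  # nearest valid neighbour must be in the region
        zf = np.where(missing & inside, fill, zf)

    use = region & np.isfinite(zf)
    if not use.any():
        return CategoryVolume(category, 0.0, n_pix, missing_fraction, 0.0, True, False)

    if (
        isinstance(plate_surface.model, OffsetPlaneModel)
        and np.isfinite(plate_surface.model.bore_radius)
    ):
        # level fill in a narrow calibrated bore: integrate as level x bore
        # area — robust to the near-rim occluding part of the liquid surface
        rows, cols = np.nonzero(use)
        zz = zf[rows, cols]
        u = (cols - k.cx) / k.fx * zz
        v = (rows - k.cy) / k.fy * zz
        h = plate_surface.model.z_vertical(u, v) - zz
        level = float(np.median(h))
        clamped = float(np.mean(h < 0.0))
        volume_ml = max(level, 0.0) * np.pi * plate_surface.model.bore_radius**2 * 1e6
        return CategoryVolume(
            category, float(volume_ml), n_pix, missing_fraction, clamped,
            low_confidence=missing_fraction > 0.5,
        )

    if isinstance(plate_surface.model, SphereModel):
        # liquid level in a spherical cavity: the remaining soup is the
        # spherical cap below the (robustly estimated) level plane
        m = plate_surface.model
        level = float(np.median(zf[use]))
        z_bottom = m.cz + m.radius
        h = np.clip(z_bottom - level, 0.0, None)
        volume_ml = float(np.pi * h * h * (3.0 * m.radius - h) / 3.0 * 1e6)
        return CategoryVolume(
            category, volume_ml, n_pix, missing_fraction, 0.0,
            low_confidence=missing_fraction > 0.5,
        )

    # gradients on a lightly smoothed copy (noise robustness); heights on raw
    z_s = _smooth_in_mask(zf, use, gradient_smooth_sigma) if gradient_smooth_sigma > 0 else zf
    dzr, dzc = _nan_gradient(np.where(use, z_s, np.nan))

    rows, cols = np.nonzero(use)
    zz = zf[rows, cols]
    a = (cols - k.cx) / k.fx
    b = (rows - k.cy) / k.fy
    ju = np.clip(zz + a * dzc[rows, cols] * k.fx, 0.0, None)
    jv = np.clip(zz + b * dzr[rows, cols] * k.fy, 0.0, None)
    footprint = ju * jv / (k.fx * k.fy)

    u = a * zz
    v = b * zz
    h = plate_surface.model.z_vertical(u, v) - zz
    clamped_fraction = float(np.mean(h < 0.0))
    h = np.clip(h, 0.0, None)

    volume_ml = float(np.sum(h * footprint) * 1e6)
    return CategoryVolume(
        category,
        volume_ml,
        n_pix,
        missing_fraction,
        clamped_fraction,
        low_confidence=missing_fraction > 0.5,
    )


# --------------------------------------------------------------------------
# fractions and intake


def consumed_fraction(
    v_before: VolumeEstimate, v_after: VolumeEstimate, category: str
) -> float:
    """(V_before - V_after) / V_before clamped to [0, 1]; a category missing
    from the after frame counts as fully consumed."""
    if category not in v_before.volumes:
        raise KeyError(f"category {category!r} absent from before-frame volumes")
    vb = v_before.volume_ml(category)
    if category not in v_after.volumes:
        return 1.0
    va = v_after.volume_ml(category)
    if vb <= 0.0:
        return 1.0 if va <= 0.0 else 0.0
    return float(np.clip((vb - va) / vb, 0.0, 1.0))


def snap_fraction(fraction: float, step: float = 0.10) -> float:
    """Optional post-hoc snap of a continuous fraction to a coarse scale."""
    return float(np.clip(np.round(fraction / step) * step, 0.0, 1.0))


@dataclass
class IntakeRecord:
    """Consumed fractions and nutrient intake for one meal."""

    fractions: dict[str, float]
    intakes: dict[str, NutrientVector]
    totals: NutrientVector
    diagnostics: dict = field(default_factory=dict)


def compute_intake(
    fractions: dict[str, float],
    scaled_menu: dict[str, NutrientVector],
) -> IntakeRecord:
    """Multiply each category's consumed fraction by its scaled nutrients.

    Meal totals sum every category except sauce, whose intake is recorded
    but discarded from the totals (as in the reference estimation protocol).
    """
    unknown = set(fractions) - set(scaled_menu)
    if unknown:
        raise KeyError(f"fractions for categories not on the menu: {sorted(unknown)}")
    intakes = {}
    totals = NutrientVector()
    for cat, frac in fractions.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"fraction for {cat!r} outside [0, 1]: {frac}")
        nv = scaled_menu[cat].scaled(frac)
        intakes[cat] = nv
        if cat != "sauce":
            totals = totals + nv
    return IntakeRecord(fractions=dict(fractions), intakes=intakes, totals=totals)


_CONTAINER_FOR_LABEL = {v: name for name, v in PLATE_LABELS.items() if v}


def estimate_meal(
    before: RGBDFrame,
    after: RGBDFrame,
    masks_before,
    masks_after,
    menu: "Menu | dict[str, NutrientVector]",
    size: MealSize,
    k: CameraIntrinsics,
    container_registry: "dict | None" = None,
) -> IntakeRecord:
    """Full pipeline: surfaces, volumes, fractions, intake for one meal.

    ``masks_*`` carry ``food_mask`` / ``plate_mask`` attributes (ground truth
    or network predictions).  Containers whose surface cannot be
    reconstructed exclude their food categories with a logged reason.
    """
    if isinstance(menu, Menu):
        scaled = {c.category: scale_nutrients(c.nutrients, size) for c in menu.components}
    else:
        scaled = {cat: scale_nutrients(nv, size) for cat, nv in menu.items()}

    cloud_b = depth_to_cloud(before, k)
    cloud_a = depth_to_cloud(after, k)
    diagnostics: dict = {"excluded": {}, "surfaces": {}, "volumes": {}}

    def surfaces(cloud, masks):
        out = {}
        for lab in np.unique(masks.plate_mask):
            if lab == 0:
                continue
            ptype = _CONTAINER_FOR_LABEL[int(lab)]
            try:
                out[ptype] = reconstruct_plate_surface(
                    cloud, masks.plate_mask, masks.food_mask, ptype, k, container_registry
                )
            except InvalidSurfaceError as exc:
                diagnostics["excluded"][ptype] = str(exc)
        return out

    surf_b = surfaces(cloud_b, masks_before)
    surf_a = surfaces(cloud_a, masks_after)
    diagnostics["surfaces"] = {
        p: {"method": s.method, "rms_m": s.fit_rms_m} for p, s in surf_b.items()
    }

    owner_b = associate_food_pixels(masks_before.plate_mask, masks_before.food_mask)
    owner_a = associate_food_pixels(masks_after.plate_mask, masks_after.food_mask)

    def volume_estimate(phase, cloud, masks, owner, surfs):
        est = VolumeEstimate(phase=phase)
        for lab in np.unique(masks.food_mask):
            if lab == 0 or lab == FOOD_LABELS["plate"]:
                continue
            cat = {v: c for c, v in FOOD_LABELS.items()}[int(lab)]
            region = masks.food_mask == lab
            owner_labels = owner[region]
            owner_lab = np.bincount(owner_labels[owner_labels > 0]).argmax() if (owner_labels > 0).any() else 0
            ptype = _CONTAINER_FOR_LABEL.get(int(owner_lab))
            if ptype is None or ptype not in surfs:
                diagnostics["excluded"].setdefault(cat, f"no valid surface for container of {cat}")
                continue
            est.volumes[cat] = estimate_food_volume(cloud, masks.food_mask, surfs[ptype], cat, k)
        return est

    vol_b = volume_estimate("before", cloud_b, masks_before, owner_b, surf_b)
    vol_a = volume_estimate("after", cloud_a, masks_after, owner_a, surf_a)
    diagnostics["volumes"] = {
        "before": {c: v.volume_ml for c, v in vol_b.volumes.items()},
        "after": {c: v.volume_ml for c, v in vol_a.volumes.items()},
    }

    after_only = set(vol_a.volumes) - set(vol_b.volumes)
    for cat in after_only:
        warnings.warn(
            f"category {cat!r} appears only in the after frame; skipped", stacklevel=2
        )

    fractions = {}
    for cat in vol_b.volumes:
        if cat not in scaled:
            diagnostics["excluded"].setdefault(cat, "not on the menu")
            continue
        fractions[cat] = consumed_fraction(vol_b, vol_a, cat)

    record = compute_intake(fractions, scaled)
    record.diagnostics = diagnostics
    return record
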