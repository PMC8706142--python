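"""Registered RGB + depth frame I/O and pinhole back-projection.

Conventions (fixed here because they must be fixed somewhere for the
intrinsics to be meaningful):

* pixel coordinates are 0-based ``(row, col)`` with pixel centres at integer
  coordinates;
* the camera frame has its origin at the optical centre, ``+z`` pointing away
  from the camera (down, for the overhead tray mount), ``+x`` along columns
  and ``+y`` along rows;
* depth maps are single-channel 16-bit PNGs whose counts convert to metres
  through ``depth_unit`` (default 1 count = 1 mm); a zero count marks a
  missing measurement.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "CameraIntrinsics",
    "RGBDFrame",
    "PointCloud",
    "read_frame",
    "write_frame",
    "depth_to_cloud",
    "project_points",
    "load_intrinsics",
    "save_intrinsics",
    "parse_frame_id",
]

DEFAULT_WIDTH = 640
DEFAULT_HEIGHT = 480


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics of the registered RGB-D pair.

    ``depth_unit`` is metres per stored depth count (0.001 for millimetre
    counts, the depth-camera convention used throughout).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT
    depth_unit: float = 0.001

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")
        if self.depth_unit <= 0:
            raise ValueError("depth_unit must be positive")

    def scaled(self, factor: float) -> "CameraIntrinsics":
        """Intrinsics for an image resampled by ``factor`` (same field of view)."""
        return CameraIntrinsics(
            fx=self.fx * factor,
            fy=self.fy * factor,
            cx=(self.cx + 0.5) * factor - 0.5,
            cy=(self.cy + 0.5) * factor - 0.5,
            width=int(round(self.width * factor)),
            height=int(round(self.height * factor)),
            depth_unit=self.depth_unit,
        )

    def ray_slopes(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel ray slopes (a, b) with x = a*z, y = b*z along each ray."""
        cols = np.arange(self.width, dtype=np.float64)
        rows = np.arange(self.height, dtype=np.float64)
        a = (cols[None, :] - self.cx) / self.fx
        b = (rows[:, None] - self.cy) / self.fy
        return np.broadcast_to(a, (self.height, self.width)).copy(), np.broadcast_to(
            b, (self.height, self.width)
        ).copy()


#: Default camera model: overhead mount at 47 cm with a 640x480 sensor whose
#: field of view frames a ~50 x 38 cm serving tray.
DEFAULT_INTRINSICS = CameraIntrinsics(fx=580.0, fy=580.0, cx=319.5, cy=239.5)


@dataclass
class RGBDFrame:
    """A registered colour + depth image pair with capture metadata."""

    rgb: np.ndarray
    depth: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        depth = np.asarray(self.depth)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError(f"rgb must be HxWx3, got shape {rgb.shape}")
        if rgb.dtype != np.uint8:
            raise ValueError(f"rgb must be 8-bit, got dtype {rgb.dtype}")
        if depth.ndim != 2:
            raise ValueError(f"depth must be HxW, got shape {depth.shape}")
        if depth.dtype != np.uint16:
            raise ValueError(f"depth must be 16-bit, got dtype {depth.dtype}")
        if rgb.shape[:2] != depth.shape:
            raise ValueError(
                f"rgb {rgb.shape[:2]} and depth {depth.shape} dimensions differ"
            )
        self.rgb = rgb
        self.depth = depth

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass
class PointCloud:
    """Back-projected depth map: one 3-D point per pixel, invalid where depth=0."""

    points: np.ndarray  # N x 3, metres, camera frame
    pixel_index: np.ndarray  # N x 2 (row, col) provenance
    valid: np.ndarray  # N boolean
    shape: tuple[int, int]  # source (H, W)

    def z_map(self) -> np.ndarray:
        """H x W map of point depths (z) with NaN at invalid pixels."""
        z = np.full(self.shape, np.nan)
        r, c = self.pixel_index[self.valid].T
        z[r, c] = self.points[self.valid, 2]
        return z


_META_REQUIRED = ("patient_id", "meal_variant", "meal_size", "timestamp", "phase")


def _validate_meta(meta: dict) -> dict:
    missing = [k for k in _META_REQUIRED if k not in meta]
    if missing:
        raise ValueError(f"frame metadata missing fields {missing}")
    if meta["phase"] not in ("before", "after"):
        raise ValueError(f"phase must be 'before' or 'after', got {meta['phase']!r}")
    return dict(meta)


def read_frame(
    rgb_path: str | Path,
    depth_path: str | Path,
    meta: dict | str | Path | None = None,
) -> RGBDFrame:
    """Read a registered RGB (8-bit PNG) + depth (16-bit PNG, mm) pair.

    ``meta`` is either a metadata mapping or the path of a JSON sidecar; if
    omitted, a ``<depth stem>.json`` sidecar next to the depth image is used.
    """
    rgb_path, depth_path = Path(rgb_path), Path(depth_path)
    for p in (rgb_path, depth_path):
        if not p.exists():
            raise FileNotFoundError(p)
    rgb = np.asarray(iio.imread(rgb_path))
    if rgb.ndim == 3 and rgb.shape[2] == 4:  # tolerate alpha
        rgb = rgb[:, :, :3]
    depth = np.asarray(iio.imread(depth_path)).astype(np.uint16)
    if meta is None:
        sidecar = depth_path.with_suffix(".json")
        meta = sidecar if sidecar.exists() else {}
    if isinstance(meta, (str, Path)):
        meta = json.loads(Path(meta).read_text())
    return RGBDFrame(rgb=rgb, depth=depth, meta=_validate_meta(meta))


def write_frame(
    frame: RGBDFrame,
    rgb_path: str | Path,
    depth_path: str | Path,
    write_meta: bool = True,
) -> None:
    """Write a frame as 8-bit RGB PNG + 16-bit depth PNG (+ JSON sidecar)."""
    rgb_path, depth_path = Path(rgb_path), Path(depth_path)
    rgb_path.parent.mkdir(parents=True, exist_ok=True)
    depth_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(rgb_path, frame.rgb)
    iio.imwrite(depth_path, frame.depth)
    if write_meta and frame.meta:
        depth_path.with_suffix(".json").write_text(json.dumps(frame.meta, indent=1))


def depth_to_cloud(frame: RGBDFrame, k: CameraIntrinsics) -> PointCloud:
    """Back-project the depth map to a 3-D point cloud in the camera frame.

    For pixel (r, c) with depth count d > 0::

        z = d * depth_unit
        x = (c - cx) * z / fx
        y = (r - cy) * z / fy

    Zero-depth pixels yield points flagged invalid (coordinates NaN).
    """
    h, w = frame.shape
    if (h, w) != (k.height, k.width):
        raise ValueError(
            f"frame shape {(h, w)} does not match intrinsics {(k.height, k.width)}"
        )
    d = frame.depth.astype(np.float64)
    z = d * k.depth_unit
    rows, cols = np.mgrid[0:h, 0:w]
    x = (cols - k.cx) * z / k.fx
    y = (rows - k.cy) * z / k.fy
    valid = frame.depth.reshape(-1) > 0
    points = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    points[~valid] = np.nan
    return PointCloud(
        points=points,
        pixel_index=np.stack([rows.reshape(-1), cols.reshape(-1)], axis=1),
        valid=valid,
        shape=(h, w),
    )


def project_points(points: np.ndarray, k: CameraIntrinsics) -> np.ndarray:
    """Forward pinhole projection: N x 3 camera-frame points -> N x 2 (row, col)."""
    pts = np.asarray(points, dtype=np.float64)
    z = pts[:, 2]
    col = pts[:, 0] / z * k.fx + k.cx
    row = pts[:, 1] / z * k.fy + k.cy
    return np.stack([row, col], axis=1)


def load_intrinsics(path: str | Path) -> CameraIntrinsics:
    data = json.loads(Path(path).read_text())
    return CameraIntrinsics(**data)


def save_intrinsics(k: CameraIntrinsics, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "fx": k.fx,
                "fy": k.fy,
                "cx": k.cx,
                "cy": k.cy,
                "width": k.width,
                "height": k.height,
                "depth_unit": k.depth_unit,
            },
            indent=1,
        )
    )


def parse_frame_id(
    name: str,
    pattern: str = r"(?P<patient_id>[^_]+)_(?P<meal_variant>[^_]+)_(?P<meal_size>[^_]+)_(?P<timestamp>[^_]+)_(?P<phase>before|after)",
) -> dict:
    """Parse capture metadata from a frame identifier.

    The acquisition protocol encodes patient, meal composition, meal size and
    time in each image's number; the exact syntax is site-specific, so the
    regular expression (with named groups matching the metadata fields) is
    supplied by configuration.  The default matches the underscore-separated
    scheme used by :mod:`trayintake.synthetic_scene`.
    """
    m = re.match(pattern, name)
    if m is None:
        raise ValueError(f"frame id {name!r} does not match pattern {pattern!r}")
    return m.groupdict()
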