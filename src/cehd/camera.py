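"""Pinhole camera model, depth back-projection, and ground-frame heights.

The measurement platform carries a forward-moving RGB-D camera mounted at a
fixed height above the ground and pitched downward toward the crop row.  This
module maps depth-image pixels to metric 3-D points in the camera frame and
converts them to heights above the ground using the mount extrinsics.

Conventions
-----------
* Camera frame: x right, y down (image down), z forward along the optical
  axis.  The pitch angle rotates the optical axis below horizontal about the
  camera x-axis.
* Pixel coordinates are 0-based with pixel centers at integer coordinates;
  boxes are half-open ``[x1, x2) x [y1, y2)`` when rasterized.
* Depth maps store unsigned integers in ``1/depth_scale`` meters (millimeters
  by default); 0 is the invalid-depth sentinel and NaN is also invalid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CameraModel",
    "DepthFrame",
    "InvalidDepthError",
    "EmptyPointCloudError",
    "backproject_pixel",
    "backproject_box",
    "ground_height",
    "horizontal_range",
    "project_point",
]


class InvalidDepthError(ValueError):
    """Raised when a pixel has no valid depth (zero / NaN sentinel)."""


class EmptyPointCloudError(ValueError):
    """Raised when a box contains no valid depth pixels to back-project."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics plus mount extrinsics.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels.
    cx, cy : float
        Principal point in pixels.
    mount_height : float
        Camera height above the ground plane in meters.
    pitch : float
        Downward tilt of the optical axis from horizontal, in radians.
    depth_scale : float
        Depth-map units per meter (1000 for millimeter maps).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    mount_height: float = 1.8
    pitch: float = math.radians(45.0)
    depth_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")
        if not 0.0 <= self.pitch < math.pi / 2:
            raise ValueError("pitch must lie in [0, pi/2)")
        if self.mount_height <= 0:
            raise ValueError("mount_height must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CameraModel":
        """Load a camera config (keys fx, fy, cx, cy, mount_height_m,
        pitch_deg, depth_scale)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            fx=float(raw["fx"]),
            fy=float(raw["fy"]),
            cx=float(raw["cx"]),
            cy=float(raw["cy"]),
            mount_height=float(raw.get("mount_height_m", 1.8)),
            pitch=math.radians(float(raw.get("pitch_deg", 45.0))),
            depth_scale=float(raw.get("depth_scale", 1000.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "fx": float(self.fx),
            "fy": float(self.fy),
            "cx": float(self.cx),
            "cy": float(self.cy),
            "mount_height_m": float(self.mount_height),
            "pitch_deg": math.degrees(self.pitch),
            "depth_scale": float(self.depth_scale),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class DepthFrame:
    """Per-pixel range image.

    ``values`` holds raw depth units (``cam.depth_scale`` per meter); 0 and
    NaN mark invalid pixels.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("depth frame must be a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def valid_mask(self) -> np.ndarray:
        vals = self.values.astype(float)
        return (vals > 0) & np.isfinite(vals)


def backproject_pixel(
    u: float, v: float, depth: float, cam: CameraModel
) -> tuple[float, float, float]:
    """Back-project one pixel + raw depth to a camera-frame point (meters).

    Raises :class:`InvalidDepthError` on a sentinel (zero / NaN) depth.
    """
    if not np.isfinite(depth) or depth <= 0:
        raise InvalidDepthError(f"no valid depth at pixel ({u}, {v})")
    z = float(depth) / cam.depth_scale
    x = (u - cam.cx) * z / cam.fx
    y = (v - cam.cy) * z / cam.fy
    return (x, y, z)


def _clip_box(
    box: tuple[float, float, float, float], shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    """Clip an (x1, y1, x2, y2) box to integer pixel bounds (half-open)."""
    h, w = shape
    x1 = max(0, int(math.floor(box[0])))
    y1 = max(0, int(math.floor(box[1])))
    x2 = min(w, int(math.ceil(box[2])))
    y2 = min(h, int(math.ceil(box[3])))
    return x1, y1, x2, y2


def backproject_box(
    depth: DepthFrame,
    box: tuple[float, float, float, float],
    cam: CameraModel,
) -> tuple[np.ndarray, int]:
    """Back-project every valid depth pixel inside a box.

    Parameters
    ----------
    box : (x1, y1, x2, y2) pixel rectangle, clipped to the image.

    Returns
    -------
    points : (N, 3) array of camera-frame points (meters), one per valid pixel.
    n_skipped : number of in-box pixels with invalid depth.

    Raises :class:`EmptyPointCloudError` when no valid pixel remains.
    """
    x1, y1, x2, y2 = _clip_box(box, depth.shape)
    if x2 <= x1 or y2 <= y1:
        raise EmptyPointCloudError("box does not intersect the image")
    patch = depth.values[y1:y2, x1:x2].astype(float)
    vv, uu = np.mgrid[y1:y2, x1:x2]
    valid = (patch > 0) & np.isfinite(patch)
    n_skipped = int(valid.size - valid.sum())
    if not valid.any():
        raise EmptyPointCloudError("no valid depth pixels inside box")
    z = patch[valid] / cam.depth_scale
    x = (uu[valid] - cam.cx) * z / cam.fx
    y = (vv[valid] - cam.cy) * z / cam.fy
    return np.column_stack([x, y, z]), n_skipped


def ground_height(points: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Height of camera-frame points above the ground plane (meters).

    With the camera pitched down by ``pitch`` about its x-axis, the vertical
    drop of a point below the camera is ``y*cos(pitch) + z*sin(pitch)``, so

        H = mount_height - (y*cos(pitch) + z*sin(pitch)).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("empty point cloud")
    drop = pts[:, 1] * math.cos(cam.pitch) + pts[:, 2] * math.sin(cam.pitch)
    return cam.mount_height - drop


def horizontal_range(points: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Ground-plane distance of each point from the camera along the view
    azimuth (meters): ``z*cos(pitch) - y*sin(pitch)``.

    Unlike the raw optical-axis depth z, this is independent of how far below
    the camera a point sits, which makes it the right scalar for separating
    planting rows at a fixed lateral spacing.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("empty point cloud")
    return pts[:, 2] * math.cos(cam.pitch) - pts[:, 1] * math.sin(cam.pitch)


@dataclass(frozen=True)
class _Pose:
    """Camera pose along the row: world position of the optical center.

    World frame: X along travel, Y lateral toward the rows, Z up.  The camera
    x-axis is aligned with world X (image right = travel direction), the
    optical axis points along +Y pitched down by ``cam.pitch``.
    """

    x: float = 0.0
    y: float = 0.0


def world_to_camera(
    point: tuple[float, float, float], cam: CameraModel, pose_x: float = 0.0
) -> tuple[float, float, float]:
    """Transform a world point (X along travel, Y lateral, Z up) into the
    camera frame for a camera at travel position ``pose_x``."""
    X, Y, Z = point
    xr = X - pose_x  # right
    f = Y  # horizontal range along azimuth
    d = cam.mount_height - Z  # vertical drop below camera
    cp, sp = math.cos(cam.pitch), math.sin(cam.pitch)
    return (xr, d * cp - f * sp, f * cp + d * sp)


def project_point(
    point: tuple[float, float, float], cam: CameraModel, pose_x: float = 0.0
) -> tuple[float, float, float] | None:
    """Project a world point to (u, v, raw_depth); ``None`` if behind the
    camera (z <= 0 after the pose transform)."""
    x, y, z = world_to_camera(point, cam, pose_x)
    if z <= 0:
        return None
    u = cam.cx + cam.fx * x / z
    v = cam.cy + cam.fy * y / z
    return (u, v, z * cam.depth_scale)
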