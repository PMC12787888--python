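"""Depth-based removal of detections in non-target planting rows.

The harvester platform drives along one crop row; the camera also sees ears
in the adjacent row one row-spacing (~0.6 m) farther away.  Those must not
enter tracking or height estimation.  Each detection gets a representative
distance from the depth pixels in the central part of its box, and boxes
farther than a threshold (default 0.5 m, halfway between the target row and
the next) are removed.

Two distance measures are supported:

* ``"horizontal"`` (default): the ground-plane distance from the camera along
  the viewing azimuth, reconstructed from depth and the mount extrinsics.
  This equals the row offset regardless of how high the ear sits, so a fixed
  threshold separates rows cleanly under a steeply pitched camera.
* ``"depth"``: the raw optical-axis depth z.  Equivalent for a near-level
  camera, but at a 45° pitch it conflates row distance with ear height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import (
    CameraModel,
    DepthFrame,
    EmptyPointCloudError,
    backproject_box,
    horizontal_range,
)
from .detection import Detection

__all__ = ["DepthFilterConfig", "InsufficientDepthError", "box_depth", "filter_by_depth"]


class InsufficientDepthError(ValueError):
    """Raised when a box has too few valid depth pixels to characterize."""


@dataclass(frozen=True)
class DepthFilterConfig:
    threshold_m: float = 0.5  # maximum kept distance (m)
    min_valid_pixels: int = 10
    shrink_fraction: float = 0.6  # central-box fraction sampled for depth
    measure: str = "horizontal"  # "horizontal" | "depth"

    def __post_init__(self) -> None:
        if self.threshold_m <= 0:
            raise ValueError("threshold_m must be positive")
        if not 0 < self.shrink_fraction <= 1:
            raise ValueError("shrink_fraction must lie in (0, 1]")
        if self.measure not in ("horizontal", "depth"):
            raise ValueError(f"unknown measure {self.measure!r}")


def shrink_box(
    box: tuple[float, float, float, float], fraction: float
) -> tuple[float, float, float, float]:
    """Central sub-box covering ``fraction`` of each side length."""
    x1, y1, x2, y2 = box
    cx, cy = (x1 + x2) / 2.0, (y1 + y2) / 2.0
    hw = (x2 - x1) * fraction / 2.0
    hh = (y2 - y1) * fraction / 2.0
    return (cx - hw, cy - hh, cx + hw, cy + hh)


def box_depth(
    depth: DepthFrame,
    box: tuple[float, float, float, float],
    cam: CameraModel,
    cfg: DepthFilterConfig = DepthFilterConfig(),
) -> float:
    """Representative distance (m) of a box: median over valid depth pixels
    inside the centrally shrunk box, using ``cfg.measure``.

    Ear boxes inevitably include background pixels at leaf or sky depth; the
    median over the box center is robust to them.  Raises
    :class:`InsufficientDepthError` below ``cfg.min_valid_pixels``.
    """
    inner = shrink_box(box, cfg.shrink_fraction)
    try:
        points, _ = backproject_box(depth, inner, cam)
    except EmptyPointCloudError as exc:
        raise InsufficientDepthError(str(exc)) from exc
    if len(points) < cfg.min_valid_pixels:
        raise InsufficientDepthError(
            f"only {len(points)} valid depth pixels (need {cfg.min_valid_pixels})"
        )
    if cfg.measure == "horizontal":
        values = horizontal_range(points, cam)
    else:
        values = points[:, 2]
    return float(np.median(values))


def filter_by_depth(
    detections: list[Detection],
    depth: DepthFrame,
    cam: CameraModel,
    cfg: DepthFilterConfig = DepthFilterConfig(),
) -> tuple[list[Detection], list[Detection]]:
    """Split detections into (kept, removed) by representative distance.

    A detection is kept iff its box distance is <= ``cfg.threshold_m``.
    Boxes with too few valid depth pixels are kept and flagged
    (``depth_flag = "insufficient"``): the filter exists to drop confirmed
    far rows, not to discard uncertain detections.  Every detection gets its
    ``box_depth_m`` attribute set when measurable.
    """
    kept: list[Detection] = []
    removed: list[Detection] = []
    for det in detections:
        try:
            d = box_depth(depth, det.xyxy, cam, cfg)
        except InsufficientDepthError:
            det.depth_flag = "insufficient"
            kept.append(det)
            continue
        det.box_depth_m = d
        if d <= cfg.threshold_m:
            kept.append(det)
        else:
            det.depth_flag = "filtered"
            removed.append(det)
    return kept, removed
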