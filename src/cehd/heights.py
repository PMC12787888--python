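"""Per-track ear height from in-box depth point clouds.

For each tracked box the depth pixels inside the (centrally shrunk) box are
back-projected to a local point cloud, depth outliers are rejected with a
median +/- k*MAD rule, each surviving point is converted to a height above
the ground using the camera mount height and pitch, and the ear height is
the median of those per-point heights.  Per-track sequences are smoothed
with a running median.

The MAD is floored at 1 mm so a perfectly constant depth patch keeps all of
its points, and the median-of-heights (rather than median-of-depths) choice
means the estimate is directly the quantity of interest — the ear's absolute
height above the ground — after the extrinsic transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import (
    CameraModel,
    DepthFrame,
    EmptyPointCloudError,
    backproject_box,
    ground_height,
)
from .depth_filter import shrink_box

__all__ = [
    "HeightConfig",
    "HeightEstimate",
    "InsufficientPointsError",
    "remove_depth_outliers",
    "estimate_height",
    "track_height_series",
]

_MAD_FLOOR_M = 1e-3  # 1 mm


class InsufficientPointsError(ValueError):
    """Too few points survive to produce a height estimate."""


@dataclass(frozen=True)
class HeightConfig:
    outlier_k: float = 3.0  # MAD multiplier for depth outlier rejection
    min_points: int = 20
    smoothing_window: int = 5  # frames, running median per track
    shrink_fraction: float = 0.8  # central box fraction sampled
    use_camera_y: bool = False  # median over camera-frame -y instead of
    # ground heights (comparison only)

    def __post_init__(self) -> None:
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")


@dataclass
class HeightEstimate:
    track_id: int
    frame: int
    height_m: float
    n_points_used: int
    n_outliers_removed: int
    box_depth_m: float


def remove_depth_outliers(points: np.ndarray, cfg: HeightConfig) -> np.ndarray:
    """Keep points whose depth lies within k*MAD of the median depth.

    The MAD is floored at 1 mm so exact clusters are never emptied.  Raises
    :class:`InsufficientPointsError` when fewer than ``cfg.min_points``
    survive.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise InsufficientPointsError("empty point cloud")
    z = pts[:, 2]
    med = np.median(z)
    mad = max(float(np.median(np.abs(z - med))), _MAD_FLOOR_M)
    keep = np.abs(z - med) <= cfg.outlier_k * mad
    if keep.sum() < cfg.min_points:
        raise InsufficientPointsError(
            f"{int(keep.sum())} points after outlier removal (need {cfg.min_points})"
        )
    return pts[keep]


def estimate_height(
    track_id: int,
    frame: int,
    box_tlwh: tuple[float, float, float, float],
    depth: DepthFrame,
    cam: CameraModel,
    cfg: HeightConfig = HeightConfig(),
) -> HeightEstimate:
    """Height estimate for one track on one frame.

    ``box_tlwh`` is the (smoothed) track box.  Raises
    :class:`InsufficientPointsError` when the box lacks usable depth; the
    caller keeps the track's previous estimate in that case.
    """
    x, y, w, h = box_tlwh
    inner = shrink_box((x, y, x + w, y + h), cfg.shrink_fraction)
    try:
        points, _ = backproject_box(depth, inner, cam)
    except EmptyPointCloudError as exc:
        raise InsufficientPointsError(str(exc)) from exc
    kept = remove_depth_outliers(points, cfg)
    n_out = len(points) - len(kept)
    if cfg.use_camera_y:
        heights = -kept[:, 1]
    else:
        heights = ground_height(kept, cam)
    return HeightEstimate(
        track_id=track_id,
        frame=frame,
        height_m=float(np.median(heights)),
        n_points_used=len(kept),
        n_outliers_removed=n_out,
        box_depth_m=float(np.median(kept[:, 2])),
    )


def running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running median; window 1 is the identity.  Edges use the
    available neighborhood."""
    v = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(v)
    for i in range(len(v)):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        out[i] = np.median(v[lo:hi])
    return out


def track_height_series(
    estimates: list[HeightEstimate], cfg: HeightConfig = HeightConfig()
) -> dict:
    """Smooth one track's height sequence and summarize it.

    Returns ``{"frames", "heights_m", "smoothed_m", "median_m", "mad_m",
    "n_frames"}``; the summary median is the plain median of the raw
    estimates.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    est = sorted(estimates, key=lambda e: e.frame)
    heights = np.array([e.height_m for e in est])
    med = float(np.median(heights))
    return {
        "frames": np.array([e.frame for e in est]),
        "heights_m": heights,
        "smoothed_m": running_median(heights, cfg.smoothing_window),
        "median_m": med,
        "mad_m": float(np.median(np.abs(heights - med))),
        "n_frames": len(est),
    }
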