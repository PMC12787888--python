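"""Synthetic RGB-D corn-field scenes with known ground truth.

The generator emulates the acquisition geometry of a row-following platform:
a depth camera mounted 1.8 m above the ground, pitched 45° down, facing the
crop rows sideways while advancing along the inter-row line.  Two planting
rows are populated with ears at known heights — the target row at the
configured lateral offset and a second row one row-spacing (0.6 m) farther —
and every frame yields:

* a 16-bit millimeter depth map (ears as constant-depth rectangles over a
  far background, nearer ears over-painting farther ones, optional
  multiplicative depth noise and background-pixel contamination),
* ground-truth boxes, identities and visibility flags,
* detector-like detections whose box noise scales as kappa*(1-c)*h with the
  drawn confidence c — the same law the adaptive filter's observation-noise
  model assumes — plus per-identity appearance embeddings, optional
  detection dropout or degradation windows, and false positives.

Ears are billboards, not meshes: the downstream pipeline only consumes
in-box depth statistics, so rectangles with contamination are a sufficient
test double (see docs/methods.md for what this does and does not emulate).

World frame: X along travel, Y lateral toward the rows, Z up.  All
randomness derives from ``cfg.seed``; per-frame streams are keyed by
(seed, frame) so frames can be produced in any order, deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .camera import CameraModel, DepthFrame, project_point, world_to_camera
from .detection import Detection

__all__ = [
    "NoiseConfig",
    "OcclusionWindow",
    "SceneConfig",
    "Ear",
    "TrueBox",
    "SceneGroundTruth",
    "generate_scene",
    "render_depth_frame",
    "generate_detections",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Detector / sensor noise model.

    ``pixel_noise_scale`` is kappa in the detection-noise law
    sigma = kappa*(1-c)*h_px; with kappa equal to the filter's position
    weight w the adaptive observation-noise model is exactly specified.
    ``depth_noise_frac`` is the multiplicative depth-noise std (the D435i is
    rated below 2 % error within 2 m); ``bg_contamination_frac`` the
    fraction of in-box pixels replaced by background depth (leaves/sky seen
    through the box); ``fp_rate`` the expected false positives per frame.
    """

    pixel_noise_scale: float = 0.05
    confidence_range: tuple[float, float] = (0.6, 0.95)
    depth_noise_frac: float = 0.01
    bg_contamination_frac: float = 0.2
    fp_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("depth_noise_frac", "bg_contamination_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class OcclusionWindow:
    """Detector failure episode: ``drop`` removes the detections of
    ``ear_ids`` for frames [start, stop] (inclusive, 0-based); ``degrade``
    forces their confidence to the low end and triples the box noise."""

    ear_ids: tuple[int, ...]
    start: int
    stop: int
    mode: str = "drop"

    def __post_init__(self) -> None:
        if self.mode not in ("drop", "degrade"):
            raise ValueError(f"unknown occlusion mode {self.mode!r}")

    def active(self, ear_id: int, frame: int) -> bool:
        return ear_id in self.ear_ids and self.start <= frame <= self.stop


def _default_camera() -> CameraModel:
    return CameraModel(fx=400.0, fy=400.0, cx=320.0, cy=240.0)


@dataclass(frozen=True)
class SceneConfig:
    n_ears_target_row: int = 20
    n_ears_far_row: int = 10
    row_spacing_m: float = 0.6
    lateral_offset_m: float = 0.4  # camera to target row (30-50 cm in the field)
    ear_height_range_m: tuple[float, float] = (0.8, 1.5)
    ear_width_m: float = 0.06
    ear_length_m: float = 0.18  # vertical extent of an ear
    ear_spacing_m: float = 0.18  # along-row spacing
    camera: CameraModel = field(default_factory=_default_camera)
    image_size: tuple[int, int] = (640, 480)  # (width, height)
    frames: int = 120
    camera_speed_m_per_frame: float = 0.04
    camera_start_x: float = -0.4
    background_depth_m: float = 4.0
    min_range_m: float = 0.2  # sensor near limit
    max_range_m: float = 3.5
    occlusion_windows: tuple[OcclusionWindow, ...] = ()
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    embedding_dim: int = 16
    embedding_cluster_std: float = 0.1
    visibility_margin_px: float = 2.0
    max_center_coverage: float = 0.4  # occluded beyond this fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.row_spacing_m <= 0:
            raise ValueError("row_spacing_m must be positive")
        if self.frames < 1:
            raise ValueError("frames must be >= 1")

    @classmethod
    def tracking_preset(cls, seed: int = 0, **overrides) -> "SceneConfig":
        """A slow-advance pass with a handful of simultaneously visible
        ears — the configuration used for tracking-quality experiments,
        where the reported (exponentially smoothed) boxes must stay on
        target (see docs/methods.md on smoothing lag)."""
        span = 7 * 0.15
        defaults = dict(
            n_ears_target_row=8,
            n_ears_far_row=4,
            ear_spacing_m=0.15,
            frames=100,
            camera_speed_m_per_frame=0.0005,
            camera_start_x=span / 2.0 - 0.025,
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class Ear:
    ear_id: int
    x: float  # along-row position (m)
    row_offset: float  # lateral distance from the camera path (m)
    height: float  # ear-center height above ground (m)
    row: str  # "target" | "far"


@dataclass
class TrueBox:
    tlwh: tuple[float, float, float, float]
    depth_m: float  # camera-frame z of the ear center
    visible: bool
    coverage: float  # fraction of the central box hidden by nearer ears


@dataclass
class SceneGroundTruth:
    cfg: SceneConfig
    ears: list[Ear]
    pose_x: np.ndarray  # camera travel position per frame
    boxes: list[dict[int, TrueBox]]  # per frame: ear_id -> TrueBox
    embedding_means: dict[int, np.ndarray]

    @property
    def target_ids(self) -> set[int]:
        return {e.ear_id for e in self.ears if e.row == "target"}

    @property
    def far_ids(self) -> set[int]:
        return {e.ear_id for e in self.ears if e.row == "far"}

    def visible_boxes(self, frame: int) -> dict[int, TrueBox]:
        return {i: b for i, b in self.boxes[frame].items() if b.visible}

    def true_heights(self) -> dict[int, float]:
        return {e.ear_id: e.height for e in self.ears}


def _ear_box(
    ear: Ear, cfg: SceneConfig, pose_x: float
) -> tuple[tuple[float, float, float, float], float] | None:
    """Project an ear's rectangle; returns (tlwh, center depth) or None when
    any corner falls behind the camera."""
    cam = cfg.camera
    hw, hl = cfg.ear_width_m / 2.0, cfg.ear_length_m / 2.0
    us, vs = [], []
    for dx in (-hw, hw):
        for dz in (-hl, hl):
            p = project_point(
                (ear.x + dx, ear.row_offset, ear.height + dz), cam, pose_x
            )
            if p is None:
                return None
            us.append(p[0])
            vs.append(p[1])
    center = world_to_camera((ear.x, ear.row_offset, ear.height), cam, pose_x)
    x1, x2 = min(us), max(us)
    y1, y2 = min(vs), max(vs)
    return (x1, y1, x2 - x1, y2 - y1), center[2]


def _center_coverage(
    box: tuple[float, float, float, float],
    nearer: list[tuple[float, float, float, float]],
    shrink: float = 0.6,
) -> float:
    """Fraction of the central sub-box hidden by the union of nearer boxes,
    computed on a rasterized grid."""
    x, y, w, h = box
    cx, cy = x + w / 2.0, y + h / 2.0
    x1, y1 = cx - shrink * w / 2.0, cy - shrink * h / 2.0
    n = 24  # grid resolution per side; area fractions only
    xs = np.linspace(x1, x1 + shrink * w, n)
    ys = np.linspace(y1, y1 + shrink * h, n)
    gx, gy = np.meshgrid(xs, ys)
    hidden = np.zeros(gx.shape, dtype=bool)
    for nx, ny, nw, nh in nearer:
        hidden |= (gx >= nx) & (gx <= nx + nw) & (gy >= ny) & (gy <= ny + nh)
    return float(hidden.mean())


def generate_scene(cfg: SceneConfig) -> SceneGroundTruth:
    """Place ears on the two rows and compute per-frame true boxes,
    depths, visibility and identity labels.  Deterministic for a fixed
    ``cfg.seed``."""
    rng = np.random.default_rng([cfg.seed, 11])
    lo, hi = cfg.ear_height_range_m
    ears: list[Ear] = []
    jitter = 0.2 * cfg.ear_spacing_m
    for i in range(cfg.n_ears_target_row):
        ears.append(
            Ear(
                ear_id=i + 1,
                x=i * cfg.ear_spacing_m + rng.uniform(-jitter, jitter),
                row_offset=cfg.lateral_offset_m,
                height=rng.uniform(lo, hi),
                row="target",
            )
        )
    span = max(1, cfg.n_ears_target_row - 1) * cfg.ear_spacing_m
    for j in range(cfg.n_ears_far_row):
        ears.append(
            Ear(
                ear_id=cfg.n_ears_target_row + j + 1,
                x=span * (j + 0.5) / max(cfg.n_ears_far_row, 1)
                + rng.uniform(-jitter, jitter),
                row_offset=cfg.lateral_offset_m + cfg.row_spacing_m,
                height=rng.uniform(lo, hi),
                row="far",
            )
        )

    emb_rng = np.random.default_rng([cfg.seed, 5])
    means: dict[int, np.ndarray] = {}
    for e in ears:
        v = emb_rng.normal(size=cfg.embedding_dim)
        means[e.ear_id] = v / np.linalg.norm(v)

    W, H = cfg.image_size
    m = cfg.visibility_margin_px
    pose_x = cfg.camera_start_x + cfg.camera_speed_m_per_frame * np.arange(cfg.frames)
    frames: list[dict[int, TrueBox]] = []
    for t in range(cfg.frames):
        per: dict[int, TrueBox] = {}
        projected: list[tuple[Ear, tuple, float]] = []
        for ear in ears:
            res = _ear_box(ear, cfg, float(pose_x[t]))
            if res is None:
                continue
            projected.append((ear, res[0], res[1]))
        for ear, tlwh, z in projected:
            x, y, w, h = tlwh
            in_image = (
                x >= m and y >= m and x + w <= W - m and y + h <= H - m
            )
            in_range = cfg.min_range_m <= z <= cfg.max_range_m
            nearer = [b for _, b, z2 in projected if z2 < z]
            cov = _center_coverage(tlwh, nearer) if nearer else 0.0
            per[ear.ear_id] = TrueBox(
                tlwh=tlwh,
                depth_m=z,
                visible=bool(
                    in_image and in_range and cov < cfg.max_center_coverage
                ),
                coverage=cov,
            )
        frames.append(per)
    return SceneGroundTruth(
        cfg=cfg, ears=ears, pose_x=pose_x, boxes=frames, embedding_means=means
    )


def render_depth_frame(gt: SceneGroundTruth, frame: int) -> DepthFrame:
    """Rasterize one frame's depth map (raw units, uint16).

    Background sits at ``background_depth_m``; each ear's projected box is
    filled with its center depth times (1 + N(0, depth_noise_frac)) per
    pixel, a ``bg_contamination_frac`` of its pixels are knocked back to
    background depth, and nearer ears over-paint farther ones.
    """
    cfg = gt.cfg
    rng = np.random.default_rng([cfg.seed, frame, 17])
    W, H = cfg.image_size
    scale = cfg.camera.depth_scale
    depth = np.full((H, W), cfg.background_depth_m * scale, dtype=float)
    order = sorted(gt.boxes[frame].items(), key=lambda kv: -kv[1].depth_m)
    for _, tb in order:
        x, y, w, h = tb.tlwh
        x1, y1 = max(0, int(math.floor(x))), max(0, int(math.floor(y)))
        x2, y2 = min(W, int(math.ceil(x + w))), min(H, int(math.ceil(y + h)))
        if x2 <= x1 or y2 <= y1:
            continue
        patch = tb.depth_m * scale * (
            1.0 + cfg.noise.depth_noise_frac * rng.standard_normal((y2 - y1, x2 - x1))
        )
        if cfg.noise.bg_contamination_frac > 0:
            mask = rng.random((y2 - y1, x2 - x1)) < cfg.noise.bg_contamination_frac
            patch[mask] = cfg.background_depth_m * scale
        depth[y1:y2, x1:x2] = patch
    return DepthFrame(np.clip(np.rint(depth), 0, 65535).astype(np.uint16))


def _occlusion_mode(cfg: SceneConfig, ear_id: int, frame: int) -> str | None:
    for wdw in cfg.occlusion_windows:
        if wdw.active(ear_id, frame):
            return wdw.mode
    return None


def generate_detections(gt: SceneGroundTruth, frame: int) -> list[Detection]:
    """Detector-like detections for one frame.

    Per visible ear: confidence c ~ U(confidence_range); box center and size
    perturbed by N(0, kappa*(1-c)*h_px).  A ``degrade`` window forces c to
    the range's low end and triples the noise; a ``drop`` window removes the
    detection.  Embeddings are drawn from the ear's unit-norm cluster mean
    with isotropic std ``embedding_cluster_std`` and re-normalized.  False
    positives arrive at Poisson rate ``fp_rate`` with random boxes and
    low-end confidence.
    """
    cfg = gt.cfg
    noise = cfg.noise
    rng = np.random.default_rng([cfg.seed, frame, 23])
    c_lo, c_hi = noise.confidence_range
    out: list[Detection] = []
    for ear_id in sorted(gt.boxes[frame]):
        tb = gt.boxes[frame][ear_id]
        if not tb.visible:
            continue
        mode = _occlusion_mode(cfg, ear_id, frame)
        if mode == "drop":
            continue
        if mode == "degrade":
            c = c_lo
            mult = 3.0
        else:
            c = float(rng.uniform(c_lo, c_hi))
            mult = 1.0
        x, y, w, h = tb.tlwh
        sigma = mult * noise.pixel_noise_scale * (1.0 - c) * h
        cx = x + w / 2.0 + rng.normal(0.0, sigma) if sigma > 0 else x + w / 2.0
        cy = y + h / 2.0 + rng.normal(0.0, sigma) if sigma > 0 else y + h / 2.0
        wn = max(2.0, w + rng.normal(0.0, sigma)) if sigma > 0 else w
        hn = max(2.0, h + rng.normal(0.0, sigma)) if sigma > 0 else h
        emb = gt.embedding_means[ear_id] + cfg.embedding_cluster_std * rng.normal(
            size=cfg.embedding_dim
        )
        emb = emb / np.linalg.norm(emb)
        out.append(
            Detection(
                frame=frame,
                box=(cx, cy, wn / hn, hn),
                confidence=c,
                embedding=emb,
            )
        )
    if noise.fp_rate > 0:
        W, H = cfg.image_size
        for _ in range(int(rng.poisson(noise.fp_rate))):
            h = float(rng.uniform(30.0, 100.0))
            a = float(rng.uniform(0.25, 0.5))
            cx = float(rng.uniform(h * a, W - h * a))
            cy = float(rng.uniform(h, H - h))
            emb = rng.normal(size=cfg.embedding_dim)
            emb = emb / np.linalg.norm(emb)
            out.append(
                Detection(
                    frame=frame,
                    box=(cx, cy, a, h),
                    confidence=float(rng.uniform(c_lo, c_lo + 0.05)),
                    embedding=emb,
                )
            )
    return out
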