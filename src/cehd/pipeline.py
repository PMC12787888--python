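"""End-to-end pipeline: score refinement -> row filter -> tracking ->
height estimation, plus the simulator output writer.

Detection is an input boundary: any MOT-dialect detection file works, so
the pipeline is detector-agnostic.  Stages run per frame in a fixed order:

1. quality-score fusion and gating (no-op when detections carry no quality
   information),
2. depth-based removal of non-target-row detections,
3. tracking-by-detection with the adaptive Kalman filter,
4. per-track ear-height estimation from the smoothed boxes.

Outputs: ``tracks.csv``, ``heights.csv``, ``height_summaries.csv``, a
``report.json`` with stage counts, and the resolved configuration
(``pipeline_config.yaml``) for provenance.  Reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as cio
from .camera import CameraModel
from .depth_filter import DepthFilterConfig, filter_by_depth
from .heights import HeightConfig, InsufficientPointsError, estimate_height, track_height_series
from .quality import QualityConfig, refine_detections
from .simulate import SceneConfig, SceneGroundTruth, generate_detections, generate_scene, render_depth_frame
from .tracker import Tracker, TrackerConfig

__all__ = ["PipelineConfig", "run_pipeline", "write_scene"]


@dataclass
class PipelineConfig:
    detections: str | Path
    camera: str | Path
    depth_dir: str | Path | None = None
    out_dir: str | Path = "cehd_out"
    depth_filter: DepthFilterConfig = field(default_factory=DepthFilterConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    heights: HeightConfig = field(default_factory=HeightConfig)
    estimate_heights: bool = True
    seed: int = 0


def _resolved_config(cfg: PipelineConfig) -> dict:
    return {
        "detections": str(cfg.detections),
        "camera": str(cfg.camera),
        "depth_dir": None if cfg.depth_dir is None else str(cfg.depth_dir),
        "out_dir": str(cfg.out_dir),
        "seed": cfg.seed,
        "depth_filter": {
            "threshold_m": cfg.depth_filter.threshold_m,
            "min_valid_pixels": cfg.depth_filter.min_valid_pixels,
            "shrink_fraction": cfg.depth_filter.shrink_fraction,
            "measure": cfg.depth_filter.measure,
        },
        "quality": {
            "k": cfg.quality.k,
            "n_bins": cfg.quality.n_bins,
            "fusion_mode": cfg.quality.fusion_mode,
            "gate_threshold": cfg.quality.gate_threshold,
        },
        "tracker": {
            "n_init": cfg.tracker.n_init,
            "max_age": cfg.tracker.max_age,
            "gating_chi2": cfg.tracker.gating_chi2,
            "max_cosine_distance": cfg.tracker.max_cosine_distance,
            "iou_threshold": cfg.tracker.iou_threshold,
            "ida_kalman": {
                "w": cfg.tracker.kalman.w,
                "eps": cfg.tracker.kalman.eps,
                "alpha": cfg.tracker.kalman.alpha,
                "adaptive": cfg.tracker.kalman.adaptive,
            },
        },
        "heights": {
            "outlier_k": cfg.heights.outlier_k,
            "min_points": cfg.heights.min_points,
            "smoothing_window": cfg.heights.smoothing_window,
            "shrink_fraction": cfg.heights.shrink_fraction,
        },
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cam = CameraModel.from_yaml(cfg.camera)
    frames = cio.read_detections(cfg.detections)
    if cfg.estimate_heights and cfg.depth_dir is None:
        raise ValueError("height estimation requires a depth directory")
    if cfg.depth_dir is not None:
        for f in range(len(frames)):
            p = cio.depth_path(cfg.depth_dir, f)
            if not p.exists():
                raise FileNotFoundError(f"missing depth frame: {p}")

    tracker = Tracker(cfg.tracker)
    records: list[dict] = []
    estimates = []
    n_suppressed = n_removed = 0
    for f, dets in enumerate(frames):
        dets, suppressed = refine_detections(dets, cfg.quality)
        n_suppressed += len(suppressed)
        depth = None
        if cfg.depth_dir is not None:
            depth = cio.read_depth(cio.depth_path(cfg.depth_dir, f))
            dets, removed = filter_by_depth(dets, depth, cam, cfg.depth_filter)
            n_removed += len(removed)
        frame_records = tracker.track_frame(f, dets)
        if cfg.estimate_heights and depth is not None:
            for r in frame_records:
                try:
                    est = estimate_height(
                        r["track_id"], f, (r["x"], r["y"], r["w"], r["h"]),
                        depth, cam, cfg.heights,
                    )
                except InsufficientPointsError:
                    continue
                estimates.append(est)
                r["height_m"] = est.height_m
                r["box_depth_m"] = est.box_depth_m
        records.extend(frame_records)

    cio.write_tracks(out / "tracks.csv", records)
    summaries: dict[int, dict] = {}
    if estimates:
        by_track: dict[int, list] = {}
        for e in estimates:
            by_track.setdefault(e.track_id, []).append(e)
        summaries = {
            tid: track_height_series(es, cfg.heights)
            for tid, es in by_track.items()
        }
        cio.write_heights(out / "heights.csv", estimates)
        cio.write_height_summaries(out / "height_summaries.csv", summaries)

    report = {
        "n_frames": len(frames),
        "n_detections": int(sum(len(d) for d in frames)),
        "n_suppressed_by_quality_gate": n_suppressed,
        "n_removed_by_depth_filter": n_removed,
        "n_track_records": len(records),
        "n_tracks": len({r["track_id"] for r in records}),
        "n_height_estimates": len(estimates),
        "seed": cfg.seed,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "pipeline_config.yaml", "w") as fh:
        yaml.safe_dump(_resolved_config(cfg), fh, sort_keys=False)
    return report


def write_scene(cfg: SceneConfig, out_dir: str | Path) -> SceneGroundTruth:
    """Generate a scene and write the full simulator output set:
    ``det.txt``, ``gt.csv``, ``gt_heights.csv``, ``depth_%06d.png``,
    ``camera.yaml`` and ``scene_config.yaml`` (resolved, incl. seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt = generate_scene(cfg)
    dets = [generate_detections(gt, f) for f in range(cfg.frames)]
    cio.write_detections(out / "det.txt", dets)
    cio.write_gt(
        out / "gt.csv",
        {f: {i: b.tlwh for i, b in gt.visible_boxes(f).items()}
         for f in range(cfg.frames)},
    )
    # tracking after the row filter is scored against the target row only
    cio.write_gt(
        out / "gt_target.csv",
        {f: {i: b.tlwh for i, b in gt.visible_boxes(f).items()
             if i in gt.target_ids}
         for f in range(cfg.frames)},
    )
    with open(out / "gt_heights.csv", "w") as fh:
        fh.write("ear_id,height_m,row\n")
        for e in gt.ears:
            fh.write(f"{e.ear_id},%.6f,{e.row}\n" % e.height)
    for f in range(cfg.frames):
        cio.write_depth(cio.depth_path(out, f), render_depth_frame(gt, f))
    cfg.camera.to_yaml(out / "camera.yaml")
    scene = {
        "n_ears_target_row": cfg.n_ears_target_row,
        "n_ears_far_row": cfg.n_ears_far_row,
        "row_spacing_m": cfg.row_spacing_m,
        "lateral_offset_m": cfg.lateral_offset_m,
        "ear_height_range_m": list(cfg.ear_height_range_m),
        "ear_spacing_m": cfg.ear_spacing_m,
        "frames": cfg.frames,
        "camera_speed_m_per_frame": cfg.camera_speed_m_per_frame,
        "camera_start_x": cfg.camera_start_x,
        "noise": {
            "pixel_noise_scale": cfg.noise.pixel_noise_scale,
            "confidence_range": list(cfg.noise.confidence_range),
            "depth_noise_frac": cfg.noise.depth_noise_frac,
            "bg_contamination_frac": cfg.noise.bg_contamination_frac,
            "fp_rate": cfg.noise.fp_rate,
        },
        "embedding_dim": cfg.embedding_dim,
        "embedding_cluster_std": cfg.embedding_cluster_std,
        "seed": cfg.seed,
    }
    with open(out / "scene_config.yaml", "w") as fh:
        yaml.safe_dump(scene, fh, sort_keys=False)
    return gt
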