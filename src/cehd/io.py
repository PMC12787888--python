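"""Readers and writers for the on-disk formats.

* Detections: MOT-challenge dialect CSV — ``frame,id,x,y,w,h,conf`` with
  optional trailing packed-vector fields (semicolon-joined floats): the
  first is the appearance embedding, the second the flattened 4 x n_bins
  regression logits.  Frame indices are 1-based on disk, 0-based in memory;
  the conversion lives here and nowhere else.
* Ground truth: MOT gt CSV (``frame,id,x,y,w,h,1,-1,-1``).
* Depth frames: single-channel 16-bit PNG per frame, millimeters, 0 =
  invalid, filename pattern ``depth_%06d.png`` (1-based frame number).
* Tracks / heights: headered CSVs with fixed float formatting so reruns are
  byte-identical.

Readers reject malformed rows with the offending line number rather than
coercing them.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .camera import DepthFrame
from .detection import Detection
from .heights import HeightEstimate

__all__ = [
    "read_detections",
    "write_detections",
    "read_depth",
    "write_depth",
    "depth_path",
    "read_mot_boxes",
    "write_gt",
    "write_tracks",
    "read_tracks",
    "write_heights",
    "write_height_summaries",
]

_FMT = "%.6f"


def _pack(vec: np.ndarray) -> str:
    return ";".join(_FMT % v for v in np.asarray(vec).ravel())


def _unpack(text: str) -> np.ndarray:
    return np.array([float(t) for t in text.split(";")])


def write_detections(path: str | Path, frames: list[list[Detection]]) -> None:
    """Write per-frame detection lists (0-based in memory, 1-based on disk)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for f, dets in enumerate(frames):
            for d in dets:
                x, y, bw, bh = d.tlwh
                row = [f + 1, -1, _FMT % x, _FMT % y, _FMT % bw, _FMT % bh,
                       _FMT % d.confidence]
                if d.embedding is not None:
                    row.append(_pack(d.embedding))
                if d.reg_logits is not None:
                    row.append(_pack(d.reg_logits))
                w.writerow(row)


def read_detections(path: str | Path) -> list[list[Detection]]:
    """Parse a MOT-dialect detection file into per-frame lists.

    Raises ``ValueError`` with the line number on malformed rows (missing
    columns, non-positive box size).  Non-monotone frame indices get a
    warning and are sorted.
    """
    per_frame: dict[int, list[Detection]] = {}
    last_frame = 0
    monotone = True
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 7:
                raise ValueError(f"{path}:{lineno}: expected >= 7 columns, got {len(row)}")
            try:
                frame = int(float(row[0]))
                x, y, bw, bh = (float(v) for v in row[2:6])
                conf = float(row[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if bw <= 0 or bh <= 0:
                raise ValueError(
                    f"{path}:{lineno}: non-positive box size (w={bw}, h={bh})"
                )
            if frame < 1:
                raise ValueError(f"{path}:{lineno}: frame index must be >= 1")
            vectors = [c for c in row[7:] if ";" in c]
            emb = _unpack(vectors[0]) if vectors else None
            if emb is not None:
                n = np.linalg.norm(emb)
                emb = emb / n if n > 0 else None
            logits = _unpack(vectors[1]) if len(vectors) > 1 else None
            det = Detection.from_tlwh(
                frame - 1, (x, y, bw, bh), conf, embedding=emb, reg_logits=logits
            )
            if frame < last_frame:
                monotone = False
            last_frame = max(last_frame, frame)
            per_frame.setdefault(frame - 1, []).append(det)
    if not monotone:
        warnings.warn(f"{path}: frame indices not monotone; sorting", stacklevel=2)
    n_frames = max(per_frame, default=-1) + 1
    return [per_frame.get(f, []) for f in range(n_frames)]


def depth_path(directory: str | Path, frame: int) -> Path:
    """Path of the depth PNG for a 0-based frame index."""
    return Path(directory) / f"depth_{frame + 1:06d}.png"


def write_depth(path: str | Path, depth: DepthFrame) -> None:
    iio.imwrite(Path(path), np.asarray(depth.values, dtype=np.uint16))


def read_depth(path: str | Path) -> DepthFrame:
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel depth PNG, got shape {arr.shape}")
    if arr.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit depth PNG, got {arr.dtype}")
    return DepthFrame(arr)


def write_gt(path: str | Path, boxes: dict[int, dict[int, tuple]]) -> None:
    """MOT ground-truth CSV from frame -> {id: tlwh} (0-based frames in)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for f in sorted(boxes):
            for i in sorted(boxes[f]):
                x, y, bw, bh = boxes[f][i]
                w.writerow([f + 1, i, _FMT % x, _FMT % y, _FMT % bw, _FMT % bh,
                            1, -1, -1])


def read_mot_boxes(path: str | Path) -> dict[int, dict[int, tuple]]:
    """frame -> {id: tlwh} from a MOT gt or track CSV (header tolerated)."""
    out: dict[int, dict[int, tuple]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if lineno == 1 and not row[0].strip().lstrip("-").isdigit():
                continue  # header
            if len(row) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
            f = int(float(row[0])) - 1
            i = int(float(row[1]))
            x, y, bw, bh = (float(v) for v in row[2:6])
            out.setdefault(f, {})[i] = (x, y, bw, bh)
    return out


_TRACK_HEADER = [
    "frame", "track_id", "x1", "y1", "w", "h", "conf", "status",
    "box_depth_m", "height_m",
]


def write_tracks(path: str | Path, records: list[dict]) -> None:
    """Track output CSV; frames 1-based on disk."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TRACK_HEADER)
        for r in records:
            w.writerow([
                r["frame"] + 1,
                r["track_id"],
                _FMT % r["x"], _FMT % r["y"], _FMT % r["w"], _FMT % r["h"],
                _FMT % r["conf"],
                r["status"],
                "" if r.get("box_depth_m") is None else _FMT % r["box_depth_m"],
                "" if r.get("height_m") is None else _FMT % r["height_m"],
            ])


def read_tracks(path: str | Path) -> dict[int, dict[int, tuple]]:
    """frame -> {track_id: tlwh} from a tracks CSV."""
    return read_mot_boxes(path)


def write_heights(path: str | Path, estimates: list[HeightEstimate]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["track_id", "frame", "height_m", "n_points", "box_depth_m"])
        for e in estimates:
            w.writerow([
                e.track_id, e.frame + 1, _FMT % e.height_m, e.n_points_used,
                _FMT % e.box_depth_m,
            ])


def write_height_summaries(path: str | Path, summaries: dict[int, dict]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["track_id", "height_median_m", "height_mad_m", "n_frames"])
        for tid in sorted(summaries):
            s = summaries[tid]
            w.writerow([tid, _FMT % s["median_m"], _FMT % s["mad_m"], s["n_frames"]])
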