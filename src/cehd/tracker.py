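"""Tracking-by-detection with the adaptive Kalman filter.

A DeepSORT-style loop: every live track is predicted forward one frame, a
matching cascade associates detections to tracks (appearance cosine distance
gated by the Mahalanobis distance of the innovation, recently-updated tracks
first), leftover tracks and detections fall back to IoU matching, matched
tracks run the adaptive Kalman update, unmatched detections spawn tentative
tracks, and tracks unseen for ``max_age`` frames are dropped.

Because the filter's observation noise adapts to detection confidence, the
Mahalanobis gate inherits the behavior: a low-confidence detection is judged
against a looser gate.

Tracks without appearance embeddings (or detections missing them) run
motion-only: Mahalanobis-gated IoU cost replaces the appearance cost.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import adaptive_kalman as ak
from .detection import Detection

__all__ = ["TrackerConfig", "Track", "Tracker", "iou", "iou_matrix"]

_INF_COST = 1e5


@dataclass(frozen=True)
class TrackerConfig:
    n_init: int = 3  # consecutive hits before a track is confirmed
    max_age: int = 30  # frames a track may coast unmatched
    gating_chi2: float = 9.4877  # chi-square 0.95 quantile, 4 dof
    max_cosine_distance: float = 0.2
    iou_threshold: float = 0.3  # minimum IoU for the fallback stage
    gallery_size: int = 100
    kalman: ak.FilterParams = field(default_factory=ak.FilterParams)

    def __post_init__(self) -> None:
        if min(self.n_init, self.max_age) < 1:
            raise ValueError("n_init and max_age must be >= 1")
        if min(self.gating_chi2, self.max_cosine_distance, self.iou_threshold) <= 0:
            raise ValueError("thresholds must be positive")


class Track:
    """One tracked target: filter state plus lifecycle bookkeeping."""

    TENTATIVE, CONFIRMED, DELETED = "tentative", "confirmed", "deleted"

    def __init__(self, track_id: int, det: Detection, cfg: TrackerConfig):
        self.track_id = track_id
        self.state = ak.initiate(det, cfg.kalman)
        self.status = Track.TENTATIVE
        self.hits = 1
        self.age = 1
        self.time_since_update = 0
        self.gallery: deque[np.ndarray] = deque(maxlen=cfg.gallery_size)
        if det.embedding is not None:
            self.gallery.append(det.embedding)
        self.last_confidence = det.confidence
        self._cfg = cfg
        # pre-predict height, for the adaptive gate noise
        self._h_prev = float(self.state.mean[3])

    def predict(self) -> None:
        self._h_prev = float(self.state.mean[3])
        self.state = ak.predict(self.state, self._cfg.kalman)
        self.age += 1
        self.time_since_update += 1

    def mark_update(self, det: Detection, state: ak.TrackState) -> None:
        self.state = state
        self.hits += 1
        self.time_since_update = 0
        self.last_confidence = det.confidence
        if det.embedding is not None:
            self.gallery.append(det.embedding)
        if self.status == Track.TENTATIVE and self.hits >= self._cfg.n_init:
            self.status = Track.CONFIRMED

    def mark_missed(self) -> None:
        if self.status == Track.TENTATIVE:
            self.status = Track.DELETED
        elif self.time_since_update > self._cfg.max_age:
            self.status = Track.DELETED

    @property
    def tlwh(self) -> tuple[float, float, float, float]:
        cx, cy, a, h = self.state.box
        w = a * h
        return (cx - w / 2.0, cy - h / 2.0, w, h)


def iou(a: tuple[float, float, float, float], b: tuple[float, float, float, float]) -> float:
    """IoU of two tlwh boxes."""
    ax1, ay1, aw, ah = a
    bx1, by1, bw, bh = b
    ix1, iy1 = max(ax1, bx1), max(ay1, by1)
    ix2, iy2 = min(ax1 + aw, bx1 + bw), min(ay1 + ah, by1 + bh)
    iw, ih = max(0.0, ix2 - ix1), max(0.0, iy2 - iy1)
    inter = iw * ih
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def iou_matrix(boxes_a: list, boxes_b: list) -> np.ndarray:
    out = np.zeros((len(boxes_a), len(boxes_b)))
    for i, a in enumerate(boxes_a):
        for j, b in enumerate(boxes_b):
            out[i, j] = iou(a, b)
    return out


class Tracker:
    """Multi-target tracker over per-frame detection lists."""

    def __init__(self, cfg: TrackerConfig | None = None):
        self.cfg = cfg or TrackerConfig()
        self.tracks: list[Track] = []
        self._next_id = 1

    # ---- distances -------------------------------------------------------

    def gating_distance(self, track: Track, det: Detection) -> float:
        """Squared Mahalanobis distance of the innovation, whitened by the
        innovation covariance with this detection's adaptive R_t."""
        p = self.cfg.kalman
        H = p.H
        if p.adaptive:
            R = ak.adaptive_noise(det.confidence, track._h_prev, p)
        else:
            R = p.fixed_observation_noise(track._h_prev)
        S = H @ track.state.covariance @ H.T + R
        innov = det.measurement - H @ track.state.mean
        try:
            sol = np.linalg.solve(S, innov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular innovation covariance") from exc
        return float(innov @ sol)

    @staticmethod
    def appearance_distance(track: Track, det: Detection) -> float | None:
        """min over the gallery of (1 - cos similarity); None if either side
        has no embedding."""
        if det.embedding is None or not track.gallery:
            return None
        sims = [float(e @ det.embedding) for e in track.gallery]
        return 1.0 - max(sims)

    # ---- association -----------------------------------------------------

    def _cost_row(self, track: Track, dets: list[Detection]) -> np.ndarray:
        """Appearance (or IoU fallback) cost for one track, gated by the
        Mahalanobis distance and the cosine threshold."""
        cfg = self.cfg
        row = np.full(len(dets), _INF_COST)
        for j, det in enumerate(dets):
            if self.gating_distance(track, det) > cfg.gating_chi2:
                continue
            d_app = self.appearance_distance(track, det)
            if d_app is None:
                ov = iou(track.tlwh, det.tlwh)
                if ov < cfg.iou_threshold:
                    continue
                row[j] = 1.0 - ov
            else:
                if d_app > cfg.max_cosine_distance:
                    continue
                row[j] = d_app
        return row

    @staticmethod
    def _solve(cost: np.ndarray) -> list[tuple[int, int]]:
        if cost.size == 0:
            return []
        rows, cols = linear_sum_assignment(cost)
        return [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] < _INF_COST]

    def associate(
        self, tracks: list[Track], dets: list[Detection]
    ) -> tuple[list[tuple[Track, Detection]], list[Track], list[Detection]]:
        """Matching cascade + IoU fallback.

        Confirmed tracks are matched level by level in order of increasing
        time-since-update, so recently seen targets get first claim on
        detections.  Tracks still unmatched after the cascade — plus all
        tentative tracks — go through a plain IoU assignment.
        """
        cfg = self.cfg
        confirmed = [t for t in tracks if t.status == Track.CONFIRMED]
        tentative = [t for t in tracks if t.status == Track.TENTATIVE]

        matches: list[tuple[Track, Detection]] = []
        det_idx = list(range(len(dets)))
        unmatched_tracks: list[Track] = []

        for level in range(cfg.max_age + 1):
            if not det_idx:
                unmatched_tracks.extend(
                    t for t in confirmed if t.time_since_update - 1 >= level
                )
                break
            level_tracks = [t for t in confirmed if t.time_since_update - 1 == level]
            if not level_tracks:
                continue
            cost = np.stack([
                self._cost_row(t, [dets[j] for j in det_idx]) for t in level_tracks
            ])
            assigned = self._solve(cost)
            hit_rows = set()
            hit_cols = set()
            for r, c in assigned:
                matches.append((level_tracks[r], dets[det_idx[c]]))
                hit_rows.add(r)
                hit_cols.add(c)
            det_idx = [j for k, j in enumerate(det_idx) if k not in hit_cols]
            unmatched_tracks.extend(
                t for r, t in enumerate(level_tracks) if r not in hit_rows
            )

        # IoU fallback: tentative tracks plus confirmed tracks missed for
        # exactly one frame (their motion estimate is still sharp).
        fallback = tentative + [
            t for t in unmatched_tracks if t.time_since_update == 1
        ]
        unmatched_tracks = [t for t in unmatched_tracks if t.time_since_update != 1]
        if fallback and det_idx:
            cand = [dets[j] for j in det_idx]
            ov = iou_matrix([t.tlwh for t in fallback], [d.tlwh for d in cand])
            cost = 1.0 - ov
            cost[ov < cfg.iou_threshold] = _INF_COST
            for r, t in enumerate(fallback):
                for k, d in enumerate(cand):
                    if self.gating_distance(t, d) > cfg.gating_chi2:
                        cost[r, k] = _INF_COST
            assigned = self._solve(cost)
            hit_rows = set()
            hit_cols = set()
            for r, c in assigned:
                matches.append((fallback[r], cand[c]))
                hit_rows.add(r)
                hit_cols.add(c)
            det_idx = [j for k, j in enumerate(det_idx) if k not in hit_cols]
            unmatched_tracks.extend(
                t for r, t in enumerate(fallback) if r not in hit_rows
            )
        else:
            unmatched_tracks.extend(fallback)

        return matches, unmatched_tracks, [dets[j] for j in det_idx]

    # ---- main loop -------------------------------------------------------

    def track_frame(self, frame: int, detections: list[Detection]) -> list[dict]:
        """Advance one frame; returns output records for tracks updated on
        this frame (smoothed boxes)."""
        for t in self.tracks:
            t.predict()

        matches, unmatched_tracks, unmatched_dets = self.associate(
            self.tracks, detections
        )

        for track, det in matches:
            # redo the filter cycle on the pre-predict state so the noise law
            # sees h_{t-1}; predict was already applied, so update directly.
            p = self.cfg.kalman
            if p.adaptive:
                R = ak.adaptive_noise(det.confidence, track._h_prev, p)
            else:
                R = p.fixed_observation_noise(track._h_prev)
            prev_smoothed = track.state.smoothed_center
            new_state = ak.update(track.state, det.measurement, R, p)
            new_state.smoothed_center = ak.smooth_center(
                prev_smoothed,
                (float(new_state.mean[0]), float(new_state.mean[1])),
                p.alpha,
            )
            track.mark_update(det, new_state)

        for track in unmatched_tracks:
            track.mark_missed()

        for det in unmatched_dets:
            self.tracks.append(Track(self._next_id, det, self.cfg))
            self._next_id += 1

        self.tracks = [t for t in self.tracks if t.status != Track.DELETED]

        records = []
        for t in self.tracks:
            if t.time_since_update == 0:
                x, y, w, h = t.tlwh
                records.append(
                    {
                        "frame": frame,
                        "track_id": t.track_id,
                        "x": x,
                        "y": y,
                        "w": w,
                        "h": h,
                        "conf": t.last_confidence,
                        "status": t.status,
                    }
                )
        return records
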