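"""Evaluation: detection P/R, height MAE and Pearson r, center-error
curves, and CLEAR-MOT / identity metrics.

Detection matching is greedy one-to-one in descending IoU at a threshold
(0.5 by convention).  MOT evaluation follows the CLEAR protocol: per frame,
correspondences from the previous frame persist while still above the IoU
threshold, remaining boxes are matched by optimal assignment maximizing IoU,
and an identity switch is counted whenever a ground-truth trajectory's
matched hypothesis id changes.  IDF1 uses the trajectory-level optimal
identity mapping (IDTP maximized over one-to-one id assignments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .tracker import iou_matrix

__all__ = [
    "MatchCounts",
    "match_boxes",
    "precision_recall",
    "mae",
    "pearson_r",
    "center_rmse",
    "mot_metrics",
    "match_track_gt_ids",
]


@dataclass
class MatchCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0


def match_boxes(
    predicted: list, truth: list, iou_threshold: float = 0.5
) -> MatchCounts:
    """Greedy one-to-one matching of tlwh boxes in descending IoU order."""
    if not predicted or not truth:
        return MatchCounts(TP=0, FP=len(predicted), FN=len(truth))
    ov = iou_matrix(predicted, truth)
    pairs = sorted(
        ((ov[i, j], i, j) for i in range(len(predicted)) for j in range(len(truth))),
        key=lambda t: -t[0],
    )
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for val, i, j in pairs:
        if val < iou_threshold:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    return MatchCounts(TP=tp, FP=len(predicted) - tp, FN=len(truth) - tp)


def precision_recall(counts: MatchCounts) -> tuple[float, float, bool]:
    """(precision, recall, degenerate): P = TP/(TP+FP), R = TP/(TP+FN).

    A zero denominator yields 0 with ``degenerate=True`` so batch reports
    never produce NaN.
    """
    degenerate = False
    if counts.TP + counts.FP > 0:
        p = counts.TP / (counts.TP + counts.FP)
    else:
        p, degenerate = 0.0, True
    if counts.TP + counts.FN > 0:
        r = counts.TP / (counts.TP + counts.FN)
    else:
        r, degenerate = 0.0, True
    return p, r, degenerate


def mae(predicted, reference) -> float:
    """Mean absolute error (units of the inputs)."""
    a = np.asarray(predicted, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("need at least one pair")
    return float(np.mean(np.abs(a - b)))


def pearson_r(predicted, reference) -> float:
    """Sample Pearson correlation; raises on constant input."""
    a = np.asarray(predicted, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    da, db = a - a.mean(), b - b.mean()
    return float((da @ db) / np.sqrt((da @ da) * (db @ db)))


def center_rmse(
    track_centers: dict[int, tuple[float, float]],
    true_centers: dict[int, tuple[float, float]],
    window: tuple[int, int] | None = None,
) -> tuple[float, dict[int, float]]:
    """RMSE (pixels) of per-frame Euclidean center errors.

    Both inputs map frame -> (x, y); only common frames count.  ``window``
    restricts to frames in [start, stop] inclusive.  Returns (rmse,
    per-frame error dict).
    """
    frames = sorted(set(track_centers) & set(true_centers))
    if window is not None:
        frames = [f for f in frames if window[0] <= f <= window[1]]
    if not frames:
        raise ValueError("no overlapping frames")
    errs = {
        f: float(np.hypot(
            track_centers[f][0] - true_centers[f][0],
            track_centers[f][1] - true_centers[f][1],
        ))
        for f in frames
    }
    rmse = float(np.sqrt(np.mean([e**2 for e in errs.values()])))
    return rmse, errs


def _frame_ids(records: dict[int, dict[int, tuple]]) -> list[int]:
    return sorted(records)


def mot_metrics(
    tracks: dict[int, dict[int, tuple[float, float, float, float]]],
    gt: dict[int, dict[int, tuple[float, float, float, float]]],
    iou_threshold: float = 0.5,
) -> dict:
    """CLEAR-MOT + identity metrics.

    Inputs map frame -> {id: tlwh box}.  Returns MOTA, IDF1, id_switches,
    plus the raw FP/FN/match counts.
    """
    frames = sorted(set(tracks) | set(gt))
    prev_match: dict[int, int] = {}  # gt id -> last matched hyp id
    fp = fn = idsw = matches = 0
    n_gt = 0
    # per-(gt id, hyp id) co-detection counts for IDF1
    pair_hits: dict[tuple[int, int], int] = {}
    gt_frames: dict[int, int] = {}
    hyp_frames: dict[int, int] = {}

    for f in frames:
        gboxes = gt.get(f, {})
        hboxes = tracks.get(f, {})
        n_gt += len(gboxes)
        for g in gboxes:
            gt_frames[g] = gt_frames.get(g, 0) + 1
        for h in hboxes:
            hyp_frames[h] = hyp_frames.get(h, 0) + 1

        gids, hids = list(gboxes), list(hboxes)
        ov = iou_matrix([gboxes[g] for g in gids], [hboxes[h] for h in hids])

        frame_match: dict[int, int] = {}
        # carry over last frame's correspondences while still valid
        free_g, free_h = set(range(len(gids))), set(range(len(hids)))
        for gi, g in enumerate(gids):
            h_prev = prev_match.get(g)
            if h_prev in hboxes:
                hi = hids.index(h_prev)
                if hi in free_h and ov[gi, hi] >= iou_threshold:
                    frame_match[g] = h_prev
                    free_g.discard(gi)
                    free_h.discard(hi)
        # optimal assignment on the rest
        if free_g and free_h:
            gl, hl = sorted(free_g), sorted(free_h)
            sub = ov[np.ix_(gl, hl)]
            cost = 1.0 - sub
            cost[sub < iou_threshold] = 1e5
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if sub[r, c] >= iou_threshold:
                    frame_match[gids[gl[r]]] = hids[hl[c]]

        for g, h in frame_match.items():
            if g in prev_match and prev_match[g] != h:
                idsw += 1
            prev_match[g] = h
            pair_hits[(g, h)] = pair_hits.get((g, h), 0) + 1
        matches += len(frame_match)
        fn += len(gboxes) - len(frame_match)
        fp += len(hboxes) - len(frame_match)

    # IDF1: optimal one-to-one identity mapping maximizing co-detections
    g_ids = sorted(gt_frames)
    h_ids = sorted(hyp_frames)
    idtp = 0
    if g_ids and h_ids:
        gain = np.zeros((len(g_ids), len(h_ids)))
        for (g, h), n in pair_hits.items():
            gain[g_ids.index(g), h_ids.index(h)] = n
        rows, cols = linear_sum_assignment(-gain)
        idtp = int(gain[rows, cols].sum())
    total_gt_boxes = sum(gt_frames.values())
    total_hyp_boxes = sum(hyp_frames.values())
    idfn = total_gt_boxes - idtp
    idfp = total_hyp_boxes - idtp
    idf1 = (
        2 * idtp / (2 * idtp + idfp + idfn) if (2 * idtp + idfp + idfn) > 0 else 0.0
    )
    mota = 1.0 - (fn + fp + idsw) / n_gt if n_gt > 0 else 0.0
    return {
        "mota": mota,
        "idf1": idf1,
        "id_switches": idsw,
        "fp": fp,
        "fn": fn,
        "matches": matches,
        "n_gt": n_gt,
    }


def match_track_gt_ids(
    tracks: dict[int, dict[int, tuple]],
    gt: dict[int, dict[int, tuple]],
    iou_threshold: float = 0.5,
) -> dict[int, int]:
    """Majority-vote identity mapping track_id -> gt id.

    Per frame, track and ground-truth boxes are matched by optimal
    assignment at the IoU threshold; each track is mapped to the gt
    identity it co-occurred with most often.
    """
    votes: dict[int, dict[int, int]] = {}
    for f in sorted(set(tracks) & set(gt)):
        tids, gids = list(tracks[f]), list(gt[f])
        if not tids or not gids:
            continue
        ov = iou_matrix([tracks[f][t] for t in tids], [gt[f][g] for g in gids])
        cost = 1.0 - ov
        cost[ov < iou_threshold] = 1e5
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if ov[r, c] >= iou_threshold:
                tally = votes.setdefault(tids[r], {})
                tally[gids[c]] = tally.get(gids[c], 0) + 1
    return {
        t: max(tally, key=lambda g: (tally[g], -g))
        for t, tally in votes.items()
    }
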