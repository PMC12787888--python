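"""Closed-form metric checks and an independent MOT oracle.

The oracle is a deliberately naive re-implementation of the CLEAR-MOT and
identity metrics (brute-force per-frame matching, exhaustive identity
mapping for small id counts) sharing no code with the package path.
"""

import itertools

import numpy as np
import pytest

from cehd.metrics import (
    MatchCounts,
    center_rmse,
    mae,
    match_boxes,
    match_track_gt_ids,
    mot_metrics,
    pearson_r,
    precision_recall,
)
from cehd.simulate import NoiseConfig, SceneConfig, generate_detections, generate_scene
from cehd.tracker import Tracker


# ---------------------------------------------------------------------------
# naive oracle
# ---------------------------------------------------------------------------

def _iou(a, b):
    ax1, ay1, aw, ah = a
    bx1, by1, bw, bh = b
    ix = max(0.0, min(ax1 + aw, bx1 + bw) - max(ax1, bx1))
    iy = max(0.0, min(ay1 + ah, by1 + bh) - max(ay1, by1))
    inter = ix * iy
    return inter / (aw * ah + bw * bh - inter) if inter > 0 else 0.0


def naive_mot(tracks, gt, thr=0.5):
    """Brute-force CLEAR-MOT: per frame, try all assignments of gt boxes to
    hypothesis boxes (with carried-over matches kept first), maximizing the
    number of matches then total IoU.  Feasible for <= 7 boxes per frame."""
    frames = sorted(set(tracks) | set(gt))
    prev = {}
    fp = fn = idsw = 0
    n_gt = 0
    pair = {}
    n_g = {}
    n_h = {}
    for f in frames:
        g = gt.get(f, {})
        h = tracks.get(f, {})
        n_gt += len(g)
        for i in g:
            n_g[i] = n_g.get(i, 0) + 1
        for j in h:
            n_h[j] = n_h.get(j, 0) + 1
        kept = {}
        for gi, hj in prev.items():
            if gi in g and hj in h and hj not in kept.values():
                if _iou(g[gi], h[hj]) >= thr:
                    kept[gi] = hj
        rem_g = [i for i in g if i not in kept]
        rem_h = [j for j in h if j not in kept.values()]
        best = {}
        best_key = (-1, -1.0)
        k = min(len(rem_g), len(rem_h))
        for r in range(k, -1, -1):
            found = False
            for gsub in itertools.combinations(rem_g, r):
                for hperm in itertools.permutations(rem_h, r):
                    ious = [_iou(g[a], h[b]) for a, b in zip(gsub, hperm)]
                    if any(v < thr for v in ious):
                        continue
                    key = (r, sum(ious))
                    if key > best_key:
                        best_key = key
                        best = dict(zip(gsub, hperm))
                        found = True
            if found:
                break
        match = {**kept, **best}
        for gi, hj in match.items():
            if gi in prev and prev[gi] != hj:
                idsw += 1
            prev[gi] = hj
            pair[(gi, hj)] = pair.get((gi, hj), 0) + 1
        fn += len(g) - len(match)
        fp += len(h) - len(match)
    gids, hids = sorted(n_g), sorted(n_h)
    idtp = 0
    if gids and hids:
        best = 0
        padded = hids + [None] * max(0, len(gids) - len(hids))
        for perm in itertools.permutations(padded, len(gids)):
            tot = sum(
                pair.get((gi, hj), 0) for gi, hj in zip(gids, perm) if hj is not None
            )
            best = max(best, tot)
        idtp = best
    tg, th = sum(n_g.values()), sum(n_h.values())
    idf1 = 2 * idtp / (2 * idtp + (tg - idtp) + (th - idtp)) if tg + th else 0.0
    mota = 1 - (fn + fp + idsw) / n_gt if n_gt else 0.0
    return {"mota": mota, "idf1": idf1, "id_switches": idsw}


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

class TestMatchBoxes:
    def test_identical_sets(self):
        boxes = [(0, 0, 10, 10), (50, 50, 10, 10)]
        c = match_boxes(boxes, boxes)
        assert (c.TP, c.FP, c.FN) == (2, 0, 0)

    def test_disjoint_sets(self):
        c = match_boxes([(0, 0, 10, 10)], [(100, 100, 10, 10)])
        assert (c.TP, c.FP, c.FN) == (0, 1, 1)

    def test_two_predictions_one_truth(self):
        truth = [(0.0, 0.0, 10.0, 10.0)]
        preds = [(0.0, 0.0, 10.0, 11.0), (0.0, 0.0, 10.0, 16.0)]  # IoU ~0.91 / 0.63
        c = match_boxes(preds, truth)
        assert (c.TP, c.FP, c.FN) == (1, 1, 0)


class TestPrecisionRecall:
    def test_hand_values(self):
        p, r, degenerate = precision_recall(MatchCounts(TP=8, FP=2, FN=2))
        assert (p, r) == (0.8, 0.8) and not degenerate

    def test_perfect(self):
        p, r, _ = precision_recall(MatchCounts(TP=5))
        assert (p, r) == (1.0, 1.0)

    def test_degenerate_zero_denominator(self):
        p, r, degenerate = precision_recall(MatchCounts())
        assert (p, r) == (0.0, 0.0) and degenerate


class TestMaePearson:
    def test_mae_hand_values(self):
        assert mae([1.0, 3.0], [2.0, 3.0]) == 0.5
        assert mae([1, 2, 3], [1, 2, 3]) == 0.0

    def test_mae_shift_invariance(self):
        a, b = np.array([1.0, 2.0, 5.0]), np.array([1.5, 1.0, 7.0])
        assert mae(a, b) == pytest.approx(mae(a + 3, b + 3))

    def test_mae_length_mismatch(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])

    def test_pearson_perfect_linear(self):
        y = np.array([1.0, 2.0, 4.0, 8.0])
        assert pearson_r(2 * y + 3, y) == pytest.approx(1.0)
        assert pearson_r(-y, y) == pytest.approx(-1.0)

    def test_pearson_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCenterRmse:
    def test_identical_series(self):
        c = {f: (float(f), 0.0) for f in range(10)}
        rmse, errs = center_rmse(c, c)
        assert rmse == 0.0 and all(v == 0 for v in errs.values())

    def test_constant_offset_3_4_5(self):
        a = {f: (0.0, 0.0) for f in range(10)}
        b = {f: (3.0, 4.0) for f in range(10)}
        rmse, _ = center_rmse(a, b)
        assert rmse == pytest.approx(5.0)

    def test_window_restriction(self):
        a = {f: (0.0, 0.0) for f in range(10)}
        b = {f: ((3.0, 4.0) if f >= 5 else (0.0, 0.0)) for f in range(10)}
        rmse_all, _ = center_rmse(a, b)
        rmse_win, errs = center_rmse(a, b, window=(5, 9))
        assert rmse_win == pytest.approx(5.0)
        assert rmse_all < rmse_win
        assert set(errs) == {5, 6, 7, 8, 9}

    def test_no_overlap_raises(self):
        with pytest.raises(ValueError):
            center_rmse({0: (0, 0)}, {5: (0, 0)})


# ---------------------------------------------------------------------------
# MOT metrics
# ---------------------------------------------------------------------------

def _shift(boxes, dx):
    return {i: (b[0] + dx, b[1], b[2], b[3]) for i, b in boxes.items()}


class TestMotMetrics:
    def test_perfect_tracking(self):
        gt = {f: {1: (f * 2.0, 0, 10, 10), 2: (100 + f * 2.0, 50, 10, 10)}
              for f in range(50)}
        m = mot_metrics(gt, gt)
        assert (m["mota"], m["idf1"], m["id_switches"]) == (1.0, 1.0, 0)

    def test_single_mid_sequence_identity_swap(self):
        """Two targets, ids swapped from frame 50 on: 2 switches and
        MOTA = 1 - 2/200."""
        gt = {f: {1: (0.0, 0, 10, 10), 2: (100.0, 0, 10, 10)} for f in range(100)}
        tracks = {}
        for f in range(100):
            if f < 50:
                tracks[f] = {1: (0.0, 0, 10, 10), 2: (100.0, 0, 10, 10)}
            else:
                tracks[f] = {2: (0.0, 0, 10, 10), 1: (100.0, 0, 10, 10)}
        m = mot_metrics(tracks, gt)
        assert m["id_switches"] == 2
        assert m["mota"] == pytest.approx(1 - 2 / 200)
        assert m["idf1"] == pytest.approx(0.5)

    def test_false_positives_and_misses_counted(self):
        gt = {f: {1: (0.0, 0, 10, 10)} for f in range(10)}
        tracks = {f: {7: (0.0, 0, 10, 10)} for f in range(10)}
        tracks[3] = {}  # one miss
        tracks[4] = {7: (0.0, 0, 10, 10), 8: (200.0, 0, 10, 10)}  # one FP
        m = mot_metrics(tracks, gt)
        assert m["fn"] == 1 and m["fp"] == 1
        assert m["mota"] == pytest.approx(1 - 2 / 10)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_naive_oracle_on_random_scenes(self, seed):
        """Randomized small scenes: package implementation equals the
        brute-force oracle exactly."""
        rng = np.random.default_rng(seed)
        n_ids = int(rng.integers(2, 5))
        frames = 30
        gt, tracks = {}, {}
        for f in range(frames):
            gt[f], tracks[f] = {}, {}
            for i in range(1, n_ids + 1):
                if rng.random() < 0.1:
                    continue  # miss in gt visibility
                box = (100.0 * i + f, 50.0 * i, 20.0, 30.0)
                gt[f][i] = box
                if rng.random() < 0.15:
                    continue  # tracker miss
                # occasional identity corruption and jitter
                tid = i if rng.random() > 0.05 else n_ids + 1
                dx = float(rng.normal(0, 2))
                tracks[f][tid] = (box[0] + dx, box[1], 20.0, 30.0)
            if rng.random() < 0.1:
                tracks[f][99] = (1000.0, 1000.0, 10.0, 10.0)  # FP
        ours = mot_metrics(tracks, gt)
        ref = naive_mot(tracks, gt)
        assert ours["id_switches"] == ref["id_switches"]
        assert ours["mota"] == pytest.approx(ref["mota"], abs=1e-9)
        assert ours["idf1"] == pytest.approx(ref["idf1"], abs=1e-9)

    def test_tracker_output_against_oracle(self):
        """End-to-end: the tracker on a small noisy scene scored identically
        by both implementations."""
        cfg = SceneConfig.tracking_preset(
            seed=2, n_ears_target_row=4, n_ears_far_row=0, frames=40
        )
        gt = generate_scene(cfg)
        tr = Tracker()
        tracks = {}
        for f in range(cfg.frames):
            for r in tr.track_frame(f, generate_detections(gt, f)):
                tracks.setdefault(f, {})[r["track_id"]] = (
                    r["x"], r["y"], r["w"], r["h"],
                )
        gtb = {f: {i: b.tlwh for i, b in gt.visible_boxes(f).items()}
               for f in range(cfg.frames)}
        ours = mot_metrics(tracks, gtb)
        ref = naive_mot(tracks, gtb)
        assert ours["mota"] == pytest.approx(ref["mota"], abs=1e-9)
        assert ours["idf1"] == pytest.approx(ref["idf1"], abs=1e-9)
        assert ours["id_switches"] == ref["id_switches"]


class TestTrackGtMapping:
    def test_majority_vote_mapping(self):
        gt = {f: {1: (0.0, 0, 10, 10), 2: (100.0, 0, 10, 10)} for f in range(10)}
        tracks = {f: {5: (0.0, 0, 10, 10), 6: (100.0, 0, 10, 10)} for f in range(10)}
        assert match_track_gt_ids(tracks, gt) == {5: 1, 6: 2}
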