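# cehd — corn-ear height detection from RGB-D field sequences

`cehd` is the post-detection stack for measuring the height of corn ears
from a row-following harvester platform: an RGB-D camera mounted 1.8 m
above the ground, pitched 45° down toward the crop row, with an external
object detector supplying per-frame ear boxes. It is aimed at agricultural
robotics / phenotyping work where the detector is a solved (GPU) problem
and the open questions are everything after it: which detections belong to
the target row, how to keep stable ear identities through occlusion and
noisy boxes, and how to turn in-box depth pixels into a height above the
ground that a cutter-bar controller can consume.

The package provides, as library modules and a `cehd` command line:

* **Row filtering** — each detection gets a representative distance from
  the median of the depth pixels in its box center; boxes beyond a 0.5 m
  threshold (the midpoint between rows spaced 0.6 m apart) are removed.
* **Quality-score fusion** — localization quality Q from top-k statistics
  of per-side box-regression distributions via an injectable MLP, fused
  with the classification score S as S′ = S + Q·O (additive) or
  S′ = S·σ(Q)·O (multiplicative), with an occlusion factor O and an output
  gate at S′ ≥ 0.75.
* **Adaptive-Kalman tracking** — DeepSORT-style association (appearance
  cosine matching, Mahalanobis gating, matching cascade, IoU fallback)
  around a constant-velocity Kalman filter whose observation noise adapts
  per dimension to detection confidence c:

      σx = max(1−c, ε)·w·h,  σy = max(1−0.8c, ε)·w·h,
      σa = max(1−0.5c, ε)·0.1,  σh = max(1−c, ε)·w·h,

  plus exponential smoothing of the reported center,
  s_t = α·s_{t−1} + (1−α)·x′_t.
* **Height estimation** — back-project in-box depth pixels, reject depth
  outliers (median ± 3·MAD), take the median of the per-point ground
  heights H = h_mount − (y·cosα + z·sinα).
* **A scene simulator** — synthetic two-row depth scenes with known ear
  heights, confidence-dependent detection noise (σ = κ(1−c)·h), occlusion
  episodes, appearance embeddings, and false positives; no external data
  needed.
* **Evaluation** — detection precision/recall (IoU 0.5), CLEAR-MOT MOTA,
  IDF1, identity switches, center-RMSE curves, height MAE and Pearson r.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Simulate a scene, run the pipeline on its detections and depth maps, and
score the result against the ground truth:

```bash
cehd simulate --seed 5 --out scene/          # writes det.txt, depth_*.png,
                                             # camera.yaml, gt*.csv
cehd track --det scene/det.txt --depth-dir scene \
           --camera scene/camera.yaml --out run/
cehd evaluate --gt scene/gt_target.csv --tracks run/tracks.csv \
              --heights run/heights.csv --gt-heights scene/gt_heights.csv
```

On the slow-advance tracking scene (`SceneConfig.tracking_preset(seed=5)`
from Python, 100 frames, 7 tracked ears) this prints:

```json
{
  "fn": 0,
  "fp": 0,
  "id_switches": 0,
  "idf1": 1.0,
  "mae_cm": 0.4428071428571442,
  "matches": 618,
  "mota": 1.0,
  "n_gt": 618,
  "n_height_pairs": 7,
  "pearson_r": 0.9999974943661804,
  "precision": 1.0,
  "recall": 1.0
}
```

Reading: every target-row ground-truth box was matched (precision = recall
= MOTA = 1.0) with no identity switches; the 400 far-row detections in the
scene were removed by the depth filter before tracking (see
`run/report.json`); per-ear median heights agree with the true heights to
0.44 cm MAE with correlation ≈ 1 under 1 % depth noise and 20 %
background contamination.

The three-way filter comparison (raw detections vs fixed-noise Kalman vs
the adaptive filter, with a detector-degradation window over frames 40–60):

```bash
cehd benchmark-occlusion --seeds 50
```

reports mean center RMSE inside the window of ≈ 4.6 px (raw), ≈ 3.3 px
(fixed-noise Kalman) and ≈ 2.0 px (adaptive + smoothing), with the
ordering adaptive < fixed < raw holding in 100 % of seeds.

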