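# Methods

This note documents the models and numerical choices behind `cehd`, the
assumptions they rest on, and what the synthetic test scenes do and do not
establish about field data.

## Problem setting

A harvesting platform carries an RGB-D camera mounted at height *h* = 1.8 m
above the ground, pitched *α* = 45° below horizontal toward a corn row at a
lateral offset of 0.3–0.5 m (0.4 m default). Rows are spaced ~0.6 m apart.
An external detector supplies per-frame ear bounding boxes with confidence
scores (and optionally appearance embeddings and box-regression
distributions). The pipeline must (1) discard detections from the adjacent,
non-target row, (2) maintain stable per-ear identities over time, and (3)
report each ear's height above the ground — the control input for cutter-bar
adjustment.

## Camera model and ground transform

A pinhole model (x right, y down, z along the optical axis) back-projects a
pixel (u, v) with raw depth *d* to

    z = d / depth_scale,   x = (u − cx)·z/fx,   y = (v − cy)·z/fy.

With the camera pitched down by α about its x-axis, a point's vertical drop
below the camera is `y·cosα + z·sinα`, so its height above ground is

    H = h − (y·cosα + z·sinα),

and its horizontal (ground-plane) distance from the camera along the view
azimuth is `f = z·cosα − y·sinα`. Depth maps are 16-bit integers in
millimeters with 0 (or NaN) marking invalid pixels, the RealSense
convention. Lens distortion and RGB–depth misalignment are out of scope
(frames are assumed pre-aligned, as the sensor SDK provides).

## Row filtering

Each detection's representative distance is the median over the valid depth
pixels in the central 60 % of its box (ear boxes contain background pixels;
the central median is robust to them). The filter keeps a detection iff
that distance is ≤ 0.5 m, the midpoint between the target row (0.4 m) and
the next row (1.0 m).

**Distance measure.** The raw optical-axis depth z mixes the row distance
with the ear's vertical drop: at α = 45°, z = (f + drop)/√2, and the drop
varies by ~0.7 m across the 0.8–1.5 m ear-height range — more than the
0.6 m row-spacing signal, so no fixed z-threshold can separate the rows.
The filter therefore thresholds the *horizontal* distance f recovered from
depth and the extrinsics, which equals the row offset independent of ear
height. The raw-z variant is available (`DepthFilterConfig(measure="depth")`)
and coincides with the horizontal measure for a near-level camera. Boxes
with fewer than `min_valid_pixels` (10) valid depths are kept and flagged
rather than dropped: the filter's job is removing confirmed far rows, not
discarding uncertain detections.

## Quality scoring and the output gate

Distributional box regression yields a discrete distribution over offset
bins per box side (16 bins by default; `n_bins` configurable). Each side's
softmax distribution is summarized by its top-k probabilities (k = 4) and
their mean; the concatenated 4·(k+1) statistic feeds a small MLP producing
a scalar quality Q. Fusion with the classification score S:

    baseline (LQE):     S′ = S + Q
    additive:           S′ = S + Q·O
    multiplicative:     S′ = S·σ(Q)·O

where O is an occlusion factor derived from S itself, and a gate emits a
box only when S′ ≥ 0.75 (inclusive). Multiplicative fusion never raises a
score, so a well-localized but low-confidence (occluded) ear waits until
occlusion lifts; additive fusion is the permissive early-training variant.

**Occlusion-factor scale.** Taken literally as O = σ(S) on a
probability-valued S, O ∈ [0.5, 0.73] and the multiplicative score is
bounded by 0.73 — below the 0.75 gate for *every* box. `logit_input=True`
computes O from the pre-sigmoid classification logit (equivalently O = S
for probability input), restoring the intended behavior: confident boxes
pass, occluded ones are deferred. The default keeps the literal σ(S) form;
any configuration that combines multiplicative fusion with the 0.75 gate
should enable `logit_input`.

The MLP is never trained here — weights are injected (`QualityMLP`), and
the whole stage is a pass-through when detections carry no quality inputs.

## Adaptive Kalman filter

State: (x, y, a, h, ẋ, ẏ, ȧ, ḣ) — box center, aspect ratio, height, and
per-frame velocities — under a constant-velocity model. Process noise uses
the height-scaled DeepSORT convention (position std h/20, velocity std
h/160 per axis; aspect 10⁻²/10⁻⁵); the control term B·u is retained in the
model but identically zero (tracking has no control input). Initiation from
an unmatched detection uses zero velocity with position std 2h/20 and
velocity std 10·h/160.

Observation noise adapts per dimension to detection confidence c ∈ [0, 1]:

    σx = max(1 − c,    ε)·w·h₍t−1₎      σy = max(1 − 0.8c, ε)·w·h₍t−1₎
    σa = max(1 − 0.5c, ε)·0.1           σh = max(1 − c,    ε)·w·h₍t−1₎

with R_t = diag(σ²), w = 0.05 (the canonical 1/20 height scaling; the
source of the per-dimension weights 1/0.8/0.5/1 is empirical and they are
configurable), ε = 0.01 the noise floor, and h₍t−1₎ the previous frame's
height estimate taken before the time update. Confident observations thus
get small R and pull the state strongly; weak ones barely perturb it.
Confidences outside [0, 1] (possible after score fusion) are clipped with a
warning. The measurement update uses the Joseph covariance form —
algebraically identical to the textbook (I − KH)P but symmetric
positive-definite by construction; equality with a plain dense-matrix
implementation to 1e-10 over 200 cycles is asserted in the tests.

The reported center is exponentially smoothed, s_t = α·s₍t−1₎ + (1−α)·x′_t
with α = 0.7. Smoothing is *reporting-only*: output boxes and height
sampling use it, while prediction and gating run on the raw posterior so
the filter's statistics stay consistent.

**Smoothing lag.** An EMA lags a target moving at v px/frame by
v·α/(1−α) ≈ 2.3v at α = 0.7. Output-side smoothing therefore suits slow
relative motion (measuring passes, the approach phase) and occlusion
windows, and will misplace boxes at high traverse speed; lower α (or α = 0)
is the right setting for fast passes. The tracking-quality experiments use
a slow-advance scene (0.0005 m/frame, lag ≈ 0.5 px) for exactly this
reason.

## Tracking

A DeepSORT-style loop around the filter: per frame, predict all tracks;
associate via a matching cascade (appearance cosine distance against a
100-deep embedding gallery, gated by the Mahalanobis distance of the
innovation at χ²₀.₉₅(4) = 9.4877 and a cosine radius of 0.2, recently seen
tracks first); leftover tentative and one-frame-stale tracks fall back to
IoU matching (threshold 0.3); matched tracks update through the adaptive
filter; unmatched detections start tentative tracks (confirmed after
n_init = 3 hits); tracks unseen for max_age = 30 frames are deleted; ids
are never reused. Because the gate uses the adaptive R_t, low-confidence
detections are judged against a looser gate — a deliberate consequence of
the noise model. Without embeddings the tracker runs motion-only
(Mahalanobis-gated IoU), so simulator output works with or without
appearance features. Assignment uses optimal bipartite matching
(`scipy.optimize.linear_sum_assignment`), making runs deterministic.

## Height estimation

For each updated track, depth pixels in the central 80 % of the (smoothed)
box are back-projected; depth outliers are removed by a median ± k·MAD rule
on z (k = 3, MAD floored at 1 mm so constant patches survive); each
surviving point is mapped to a ground height; the estimate is the median of
those heights. The median is taken over *heights*, not depths: only the
ground-frame median is the quantity of interest after the extrinsic
transform (a camera-frame variant exists behind `use_camera_y` for
comparison). Per-track series get a running median (window 5) and a
median/MAD summary. Estimates need ≥ 20 surviving points; otherwise the
frame is skipped and the track keeps its last value.

A small systematic bias (≈ 4 mm at the default geometry) remains because
the detector box is the perspective projection of the ear's extent: the box
center's image row is not exactly the projection of the ear's 3-D center.
It is well below the agronomically relevant tolerance and included in the
reported errors.

## Synthetic scenes

The simulator reproduces the acquisition geometry: two rows of ears
(heights uniform in 0.8–1.5 m) at 0.4 m / 1.0 m lateral distance, camera
advancing along the row. Ears are constant-depth billboards: the pipeline
consumes only in-box depth statistics, so rectangles with (a)
multiplicative per-pixel depth noise (1 %, the sensor's rated class),
(b) 20 % background-pixel contamination, and (c) painter's-order occlusion
are a sufficient test double. An ear is visible when its box lies inside
the image, its range is within 0.2–3.5 m, and less than 40 % of its central
box is covered by nearer ears.

Detections follow the noise law σ = κ(1−c)·h with κ = 0.05 and confidence
drawn from U(0.6, 0.95) — matching the filter's observation model exactly
(κ = w), so the adaptive filter is correctly specified outside degradation
windows. Occlusion windows either drop detections or degrade them
(confidence forced to the low end, noise tripled — under-specified for the
filter on purpose). Embeddings come from per-identity unit-norm cluster
means with isotropic std 0.1 in 16 dimensions, mimicking a re-identification
network's separable features. All randomness derives from the scene seed,
with per-frame streams keyed by (seed, frame) so any frame can be generated
independently and deterministically.

Two standard configurations: the default *traverse* (20 target + 10 far
ears, 120 frames at 0.04 m/frame — every ear enters and leaves the view;
used for row-filter and height experiments) and the *slow-advance preset*
(8 + 4 ears, 100 frames at 0.0005 m/frame; used for tracking quality, see
the smoothing-lag note). The three-way filter benchmark uses a single-ear
slow-advance scene with a degrade window over frames 40–60.

**What passing these scenes does not show:** real fields have leaf/stalk
geometry, correlated depth artifacts, detector biases that do not follow
σ ∝ (1−c)h, appearance drift, and wind motion. The synthetic results
validate the algorithms' correctness and their behavior under the stated
noise models, not field-level accuracy figures.

## Evaluation

Detection P/R uses greedy one-to-one IoU matching at 0.5. MOT evaluation
follows CLEAR: correspondences persist across frames while IoU ≥ 0.5,
remaining boxes match by per-frame optimal assignment, identity switches
count on matched-identity change; MOTA = 1 − (FN+FP+IDSW)/GT. IDF1 uses
the global one-to-one identity mapping maximizing co-detections. Height
accuracy is MAE and Pearson r between per-ear median estimates and true
heights. Zero-denominator P/R returns 0 with a degenerate flag rather than
NaN. After row filtering, tracking is scored against target-row-only ground
truth — far-row ears are removed by design.

## Problem sizes

Experiment defaults (also used by `scripts/acceptance.py`): 50 seeds for
the filter-ordering benchmark, 20 seeds × 100 frames for tracking quality,
10 seeds for row-filter exactness, one 120-frame traverse per noise
condition for height recovery. These sizes give stable orderings and
sub-percent metric jitter while keeping a full run in the low minutes on
one core.
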