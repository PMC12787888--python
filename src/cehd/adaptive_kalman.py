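"""Independent-dimension adaptive Kalman filter for box tracking.

A constant-velocity Kalman filter over the 8-dimensional state

    (x, y, a, h, vx, vy, va, vh)

where (x, y) is the box center in pixels, ``a`` the width/height aspect
ratio, ``h`` the box height in pixels, and the second half their per-frame
velocities.  Two departures from the fixed-noise filter used by classic
DeepSORT:

1.  **Confidence-adaptive observation noise.**  Detector output quality
    varies with occlusion, lighting and scale.  The observation-noise
    standard deviations are recomputed per update from the detection
    confidence c in [0, 1], independently per dimension:

        sigma_x = max(1 - c,     eps) * w * h_prev
        sigma_y = max(1 - 0.8*c, eps) * w * h_prev
        sigma_a = max(1 - 0.5*c, eps) * 0.1
        sigma_h = max(1 - c,     eps) * w * h_prev

    with R_t = diag(sigma^2), h_prev the previous-frame height estimate, w a
    position-normalization weight and eps a lower bound keeping R_t positive
    as c -> 1.  High-confidence observations thus pull the state strongly;
    low-confidence ones barely perturb it.

2.  **Exponential center smoothing.**  The reported center is smoothed as
    s_t = alpha * s_{t-1} + (1 - alpha) * x'_t, damping residual jitter.
    Smoothing affects reporting (output boxes, depth sampling) only; the raw
    posterior mean drives prediction and gating so the filter's statistics
    stay consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .detection import Detection

__all__ = ["FilterParams", "TrackState", "initiate", "predict", "adaptive_noise", "update", "smooth_center", "step"]

_NDIM = 4  # observed dimensions


def _cv_transition(ndim: int = _NDIM) -> np.ndarray:
    F = np.eye(2 * ndim)
    for i in range(ndim):
        F[i, ndim + i] = 1.0
    return F


@dataclass(frozen=True)
class FilterParams:
    """Filter configuration.

    ``w`` is the position normalization weight scaling pixel-space noise with
    box height (default 1/20, the canonical DeepSORT scaling); ``eps`` the
    observation-noise lower bound; ``alpha`` the center-smoothing
    coefficient (0 = no smoothing, 1 = frozen).  ``beta`` holds the four
    per-dimension confidence weights in max(1 - beta_i * c, eps).
    ``adaptive=False`` reverts to the fixed-R filter (c ignored) for
    baseline comparisons.
    """

    w: float = 0.05
    eps: float = 0.01
    alpha: float = 0.7
    beta: tuple[float, float, float, float] = (1.0, 0.8, 0.5, 1.0)
    std_weight_velocity: float = 1.0 / 160.0
    adaptive: bool = True
    F: np.ndarray = field(default_factory=_cv_transition, repr=False)
    H: np.ndarray = field(
        default_factory=lambda: np.eye(_NDIM, 2 * _NDIM), repr=False
    )
    # Control term B @ u of the prediction model; tracking has no control
    # input so it defaults to zero.
    Bu: np.ndarray = field(default_factory=lambda: np.zeros(2 * _NDIM), repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.eps <= 0 or self.w <= 0:
            raise ValueError("w and eps must be positive")

    def process_noise(self, h: float) -> np.ndarray:
        """Process-noise covariance Q, height-scaled per the DeepSORT
        convention (position std w*h, velocity std h/160, aspect 1e-2/1e-5)."""
        std = np.array(
            [
                self.w * h,
                self.w * h,
                1e-2,
                self.w * h,
                self.std_weight_velocity * h,
                self.std_weight_velocity * h,
                1e-5,
                self.std_weight_velocity * h,
            ]
        )
        return np.diag(std**2)

    def fixed_observation_noise(self, h: float) -> np.ndarray:
        """Constant R of the non-adaptive baseline filter."""
        std = np.array([self.w * h, self.w * h, 1e-1, self.w * h])
        return np.diag(std**2)


@dataclass
class TrackState:
    """Kalman state: 8-vector mean, 8x8 covariance, smoothed center."""

    mean: np.ndarray
    covariance: np.ndarray
    smoothed_center: tuple[float, float]

    def copy(self) -> "TrackState":
        return TrackState(
            self.mean.copy(), self.covariance.copy(), tuple(self.smoothed_center)
        )

    @property
    def box(self) -> tuple[float, float, float, float]:
        """(cx, cy, a, h) using the smoothed center."""
        return (
            self.smoothed_center[0],
            self.smoothed_center[1],
            float(self.mean[2]),
            float(self.mean[3]),
        )


def initiate(det: Detection, params: FilterParams) -> TrackState:
    """State from an unassociated detection: zero velocity, diagonal
    covariance scaled by box height."""
    x, y, a, h = det.box
    if h <= 0 or a <= 0:
        raise ValueError("detection must have positive aspect and height")
    mean = np.array([x, y, a, h, 0.0, 0.0, 0.0, 0.0])
    std = np.array(
        [
            2 * params.w * h,
            2 * params.w * h,
            1e-2,
            2 * params.w * h,
            10 * params.std_weight_velocity * h,
            10 * params.std_weight_velocity * h,
            1e-5,
            10 * params.std_weight_velocity * h,
        ]
    )
    return TrackState(mean, np.diag(std**2), (x, y))


def predict(state: TrackState, params: FilterParams) -> TrackState:
    """Time update: mean' = F mean (+ B u), cov' = F cov F^T + Q."""
    h = float(state.mean[3])
    Q = params.process_noise(h)
    mean = params.F @ state.mean + params.Bu
    cov = params.F @ state.covariance @ params.F.T + Q
    cov = 0.5 * (cov + cov.T)
    return TrackState(mean, cov, state.smoothed_center)


def adaptive_noise(c: float, h_prev: float, params: FilterParams) -> np.ndarray:
    """Confidence-weighted observation-noise covariance R_t (4x4 diagonal)."""
    if h_prev <= 0:
        raise ValueError("h_prev must be positive")
    if not 0.0 <= c <= 1.0:
        warnings.warn(
            f"detection confidence {c} outside [0, 1]; clipping", stacklevel=2
        )
        c = float(np.clip(c, 0.0, 1.0))
    b = params.beta
    scale = np.array(
        [params.w * h_prev, params.w * h_prev, 0.1, params.w * h_prev]
    )
    std = np.maximum(1.0 - np.asarray(b) * c, params.eps) * scale
    return np.diag(std**2)


def update(
    state: TrackState, z: np.ndarray, R: np.ndarray, params: FilterParams
) -> TrackState:
    """Measurement update with gain K = P H^T (H P H^T + R)^-1.

    The posterior covariance uses the Joseph form, which is algebraically
    identical to (I - K H) P but stays symmetric positive-definite.
    """
    z = np.asarray(z, dtype=float)
    H = params.H
    P = state.covariance
    S = H @ P @ H.T + R
    try:
        K = np.linalg.solve(S.T, (P @ H.T).T).T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate R
        raise np.linalg.LinAlgError(
            f"singular innovation covariance; state mean={state.mean}"
        ) from exc
    innovation = z - H @ state.mean
    mean = state.mean + K @ innovation
    IKH = np.eye(len(state.mean)) - K @ H
    cov = IKH @ P @ IKH.T + K @ R @ K.T
    cov = 0.5 * (cov + cov.T)
    return TrackState(mean, cov, state.smoothed_center)


def smooth_center(
    prev_smoothed: tuple[float, float],
    updated: tuple[float, float],
    alpha: float,
) -> tuple[float, float]:
    """Exponential smoothing s_t = alpha*s_{t-1} + (1-alpha)*x'_t per axis."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return (
        alpha * prev_smoothed[0] + (1.0 - alpha) * updated[0],
        alpha * prev_smoothed[1] + (1.0 - alpha) * updated[1],
    )


def step(
    state: TrackState, det: Detection | None, params: FilterParams
) -> TrackState:
    """One filter cycle: predict, then (if a detection arrived) adapt the
    observation noise to its confidence, update, and smooth the center.

    The height feeding the noise law is the *previous frame's* estimate,
    taken before the time update.  Without a detection only the prediction
    runs and the smoothed center is left untouched.
    """
    h_prev = float(state.mean[3])
    predicted = predict(state, params)
    if det is None:
        return predicted
    if params.adaptive:
        R = adaptive_noise(det.confidence, h_prev, params)
    else:
        R = params.fixed_observation_noise(h_prev)
    updated = update(predicted, det.measurement, R, params)
    updated.smoothed_center = smooth_center(
        state.smoothed_center,
        (float(updated.mean[0]), float(updated.mean[1])),
        params.alpha,
    )
    return updated
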