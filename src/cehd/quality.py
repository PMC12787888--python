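"""Box-quality scoring and occlusion-aware score fusion.

Distributional box regression predicts, for each of the four box sides, a
discrete probability distribution over offset bins.  A sharp distribution
means a confidently localized side; a flat one means localization
uncertainty.  Localization quality estimation (LQE) summarizes each side's
softmax distribution by its top-k probabilities plus their mean, feeds the
concatenated statistic through a small MLP to get a quality score Q, and
refines the classification score S:

    LQE (additive):          S' = S + Q

The occlusion-aware extension (AQE) adds a factor O = sigmoid(S) derived
from the classification score itself, so that a well-localized but
low-confidence box — typically a partially occluded ear — cannot be promoted:

    additive fusion:         S' = S + Q * O
    multiplicative fusion:   S' = S * sigmoid(Q) * O

Multiplicative fusion never raises a score (both factors are <= 1), and a
final gate emits a box only when S' reaches a threshold (default 0.75);
suppressed ears re-emerge once occlusion lifts and S recovers.

Training the quality MLP is out of scope: weights are injected through
:class:`QualityConfig`.  Without weights the stage is a pass-through.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detection import Detection

__all__ = [
    "QualityConfig",
    "QualityMLP",
    "distribution_stat",
    "quality_score",
    "lqe_score",
    "occlusion_factor",
    "aqe_score",
    "gate",
    "refine_detections",
]


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float))))


@dataclass
class QualityMLP:
    """Injectable quality head: a stack of linear layers with ReLU between.

    ``layers`` is a sequence of (W, b) pairs; a single pair is a plain linear
    map Q = W @ stat + b.  Output is squeezed to a scalar.
    """

    layers: Sequence[tuple[np.ndarray, np.ndarray]]

    def __call__(self, stat: np.ndarray) -> float:
        x = np.asarray(stat, dtype=float)
        for i, (W, b) in enumerate(self.layers):
            W = np.atleast_2d(np.asarray(W, dtype=float))
            b = np.atleast_1d(np.asarray(b, dtype=float))
            if W.shape[1] != x.shape[-1]:
                raise ValueError(
                    f"layer {i}: weight expects input {W.shape[1]}, got {x.shape[-1]}"
                )
            x = W @ x + b
            if i < len(self.layers) - 1:
                x = np.maximum(x, 0.0)
        if x.size != 1:
            raise ValueError("quality MLP must end in a single output unit")
        return float(x.reshape(()))

    @classmethod
    def random(
        cls, in_dim: int, hidden: int = 64, seed: int = 0, scale: float = 0.1
    ) -> "QualityMLP":
        """A seeded random one-hidden-layer head (for tests and demos)."""
        rng = np.random.default_rng(seed)
        W1 = rng.normal(0.0, scale, (hidden, in_dim))
        b1 = np.zeros(hidden)
        W2 = rng.normal(0.0, scale, (1, hidden))
        b2 = np.zeros(1)
        return cls(layers=[(W1, b1), (W2, b2)])


@dataclass
class QualityConfig:
    k: int = 4  # top-k probabilities kept per side
    n_bins: int = 16  # regression bins per side
    mlp: QualityMLP | None = None
    fusion_mode: str = "multiplicative"  # "additive" | "multiplicative"
    gate_threshold: float = 0.75
    clip_scores: bool = False  # clip fused score to [0, 1]
    # Occlusion factor from the pre-sigmoid classification logit (O = S for a
    # probability-valued score) instead of O = sigmoid(S).  With the latter,
    # O <= 0.731 for S in [0, 1] and multiplicative fusion can never reach a
    # 0.75 gate; the logit form restores the intended "high-S passes,
    # occluded low-S waits" behavior.
    logit_input: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.n_bins:
            raise ValueError(f"k={self.k} must lie in [1, n_bins={self.n_bins}]")
        if self.fusion_mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown fusion mode {self.fusion_mode!r}")
        if not 0.0 <= self.gate_threshold <= 1.0:
            raise ValueError("gate_threshold must lie in [0, 1]")


def distribution_stat(logits: np.ndarray, k: int) -> np.ndarray:
    """Statistic of the four per-side regression distributions.

    ``logits`` has shape (4, n_bins).  Each side is softmax-normalized, its
    top-k probabilities (descending) and their mean are taken, and the four
    per-side blocks are concatenated: output length 4*(k+1).
    """
    logits = np.asarray(logits, dtype=float)
    if logits.ndim != 2 or logits.shape[0] != 4:
        raise ValueError(f"expected (4, n_bins) logits, got {logits.shape}")
    n_bins = logits.shape[1]
    if k > n_bins:
        raise ValueError(f"k={k} exceeds n_bins={n_bins}")
    shifted = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    topk = -np.sort(-probs, axis=1)[:, :k]
    stat = np.concatenate([topk, topk.mean(axis=1, keepdims=True)], axis=1)
    return stat.reshape(-1)


def quality_score(stat: np.ndarray, cfg: QualityConfig) -> float:
    """Q = MLP(stat); deterministic given the injected weights."""
    if cfg.mlp is None:
        raise ValueError("no quality MLP weights configured")
    return cfg.mlp(np.asarray(stat, dtype=float))


def lqe_score(s: float, q: float) -> float:
    """Baseline additive refinement S' = S + Q."""
    return float(s + q)


def occlusion_factor(s: float, logit_input: bool = False) -> float:
    """O = sigmoid(S): monotone in the classification score, so occluded
    (low-S) boxes receive a smaller fusion weight.

    With ``logit_input`` the score is treated as the pre-sigmoid
    classification logit, i.e. for a probability-valued S the factor is
    sigmoid(logit(S)) = S itself, spanning the full [0, 1] range.
    """
    if logit_input:
        s = float(np.clip(s, 1e-9, 1 - 1e-9))
        return s
    return _sigmoid(s)


def aqe_score(s: float, q: float, o: float, mode: str) -> float:
    """Occlusion-aware fusion of classification score S and quality Q.

    additive:        S' = S + Q * O
    multiplicative:  S' = S * sigmoid(Q) * O
    """
    if mode == "additive":
        return float(s + q * o)
    if mode == "multiplicative":
        return float(s * _sigmoid(q) * o)
    raise ValueError(f"unknown fusion mode {mode!r}")


def gate(s_prime: float, cfg: QualityConfig) -> bool:
    """Emit a box iff its fused score reaches the threshold (inclusive)."""
    return s_prime >= cfg.gate_threshold


def refine_detections(
    detections: list[Detection], cfg: QualityConfig
) -> tuple[list[Detection], list[Detection]]:
    """Apply quality fusion + gate to a detection list.

    Detections carrying ``reg_logits`` (with configured MLP weights) or a
    precomputed ``quality_q`` are re-scored and gated; detections with
    neither pass through unchanged (the stage is a no-op without quality
    inputs).  Returns (emitted, suppressed).
    """
    emitted: list[Detection] = []
    suppressed: list[Detection] = []
    for det in detections:
        q: float | None = det.quality_q
        if q is None and det.reg_logits is not None and cfg.mlp is not None:
            stat = distribution_stat(det.reg_logits.reshape(4, -1), cfg.k)
            q = quality_score(stat, cfg)
        if q is None:
            emitted.append(det)
            continue
        s = det.confidence
        s_prime = aqe_score(s, q, occlusion_factor(s, cfg.logit_input), cfg.fusion_mode)
        if cfg.clip_scores:
            s_prime = float(np.clip(s_prime, 0.0, 1.0))
        det.quality_q = q
        det.confidence = s_prime
        (emitted if gate(s_prime, cfg) else suppressed).append(det)
    return emitted, suppressed
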