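"""Frame-level detection record shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Detection"]


@dataclass
class Detection:
    """One detector output on one frame.

    The box is stored as (x, y, a, h): center position in pixels, aspect
    ratio w/h, and box height in pixels — the representation the tracking
    filter estimates.  ``tlwh`` gives the (top-left x, top-left y, width,
    height) view used by the on-disk MOT dialect.

    Optional payloads: a unit-norm appearance embedding, per-side box
    regression logits (4 x n_bins) for quality scoring, and the
    representative box depth attached by the row filter.
    """

    frame: int
    box: tuple[float, float, float, float]  # (cx, cy, aspect, height)
    confidence: float
    embedding: np.ndarray | None = None
    reg_logits: np.ndarray | None = None
    quality_q: float | None = None
    box_depth_m: float | None = None
    depth_flag: str | None = None  # "filtered" / "insufficient" / None

    def __post_init__(self) -> None:
        cx, cy, a, h = self.box
        if h <= 0 or a <= 0:
            raise ValueError(f"invalid box (a={a}, h={h}): a and h must be > 0")
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
            n = float(np.linalg.norm(self.embedding))
            if abs(n - 1.0) > 1e-6:
                raise ValueError("embedding must be unit-norm")
        if self.reg_logits is not None:
            self.reg_logits = np.asarray(self.reg_logits, dtype=float)

    @property
    def tlwh(self) -> tuple[float, float, float, float]:
        cx, cy, a, h = self.box
        w = a * h
        return (cx - w / 2.0, cy - h / 2.0, w, h)

    @property
    def xyxy(self) -> tuple[float, float, float, float]:
        x, y, w, h = self.tlwh
        return (x, y, x + w, y + h)

    @classmethod
    def from_tlwh(
        cls,
        frame: int,
        tlwh: tuple[float, float, float, float],
        confidence: float,
        **kwargs,
    ) -> "Detection":
        x, y, w, h = tlwh
        if w <= 0 or h <= 0:
            raise ValueError(f"invalid tlwh box (w={w}, h={h})")
        return cls(
            frame=frame,
            box=(x + w / 2.0, y + h / 2.0, w / h, h),
            confidence=confidence,
            **kwargs,
        )

    @property
    def measurement(self) -> np.ndarray:
        """The 4-vector (x, y, a, h) fed to the Kalman filter."""
        return np.asarray(self.box, dtype=float)
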