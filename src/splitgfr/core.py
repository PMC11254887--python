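"""Shared domain types for the split-GFR pipeline.

All images live on the raw acquisition grid (default 64x64) unless stated
otherwise.  Masks are boolean numpy arrays; dynamic count data is a
``(n_frames, rows, cols)`` array.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

Side = Literal["left", "right"]

__all__ = [
    "PatientInfo",
    "AcquisitionMeta",
    "RoiSet",
    "DynamicRenogram",
    "Side",
]


@dataclass(frozen=True)
class PatientInfo:
    """Anthropometrics feeding the depth and body-surface-area formulas."""

    age: int
    sex: Literal["male", "female"]
    weight_kg: float
    height_cm: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not (self.weight_kg > 0 and np.isfinite(self.weight_kg)):
            raise ValueError(f"weight must be positive and finite, got {self.weight_kg}")
        if not (self.height_cm > 0 and np.isfinite(self.height_cm)):
            raise ValueError(f"height must be positive and finite, got {self.height_cm}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition protocol parameters plus syringe dose bookkeeping.

    ``syringe_pre_counts``/``syringe_post_counts`` are camera counts of the
    syringe measured at ``t_pre``/``t_post``; ``t_inj`` is the injection time.
    All three timestamps are seconds on a common clock.
    """

    frame_duration_s: float = 15.0
    n_frames: int = 80
    matrix_size: int = 64
    zoom: float = 1.45
    injected_activity_MBq: float = 185.0
    syringe_pre_counts: float = 2_200_000.0
    syringe_post_counts: float = 200_000.0
    t_pre: float = 0.0
    t_post: float = 0.0
    t_inj: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames <= 0 or self.frame_duration_s <= 0:
            raise ValueError("n_frames and frame_duration_s must be positive")
        if self.syringe_post_counts < 0 or self.syringe_pre_counts < self.syringe_post_counts:
            raise ValueError("require syringe_pre_counts >= syringe_post_counts >= 0")
        if not (self.t_pre <= self.t_inj <= self.t_post):
            raise ValueError("require t_pre <= t_inj <= t_post")

    @property
    def total_duration_s(self) -> float:
        return self.n_frames * self.frame_duration_s

    def frame_mid_times(self) -> np.ndarray:
        """Mid-frame acquisition times in seconds since injection."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration_s


def _as_mask(m: np.ndarray) -> np.ndarray:
    a = np.asarray(m)
    if a.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {a.shape}")
    return a.astype(bool)


@dataclass
class RoiSet:
    """The four ROI masks driving the Gates computation.

    Kidney masks must be disjoint from each other and from both background
    masks.  ``provenance`` records how the set was obtained.
    """

    kidney_left: np.ndarray
    kidney_right: np.ndarray
    bg_left: np.ndarray
    bg_right: np.ndarray
    provenance: Literal["manual-report", "deep-learning", "auto-background", "phantom-truth"] = "phantom-truth"

    def __post_init__(self) -> None:
        self.kidney_left = _as_mask(self.kidney_left)
        self.kidney_right = _as_mask(self.kidney_right)
        self.bg_left = _as_mask(self.bg_left)
        self.bg_right = _as_mask(self.bg_right)
        shapes = {m.shape for m in self.masks().values()}
        if len(shapes) != 1:
            raise ValueError(f"all masks must share one grid, got shapes {shapes}")

    def masks(self) -> dict[str, np.ndarray]:
        return {
            "kidney_left": self.kidney_left,
            "kidney_right": self.kidney_right,
            "bg_left": self.bg_left,
            "bg_right": self.bg_right,
        }

    def validate_disjoint(self) -> None:
        """Raise if a kidney mask overlaps the other kidney or any background."""
        if np.any(self.kidney_left & self.kidney_right):
            raise ValueError("kidney masks overlap")
        for side, bg in (("left", self.bg_left), ("right", self.bg_right)):
            if np.any(self.kidney_left & bg) or np.any(self.kidney_right & bg):
                raise ValueError(f"bg_{side} overlaps a kidney mask")

    def kidney(self, side: Side) -> np.ndarray:
        return self.kidney_left if side == "left" else self.kidney_right

    def bg(self, side: Side) -> np.ndarray:
        return self.bg_left if side == "left" else self.bg_right

    def copy(self) -> "RoiSet":
        return RoiSet(
            self.kidney_left.copy(),
            self.kidney_right.copy(),
            self.bg_left.copy(),
            self.bg_right.copy(),
            self.provenance,
        )


@dataclass
class DynamicRenogram:
    """A dynamic renal acquisition: per-frame count grids plus metadata.

    Counts are non-negative; noiseless simulations may carry float expected
    counts, sampled/acquired data carries integers.
    """

    counts: np.ndarray
    meta: AcquisitionMeta
    patient: PatientInfo
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError(f"counts must be (n_frames, rows, cols), got {self.counts.shape}")
        n, r, c = self.counts.shape
        if n != self.meta.n_frames:
            raise ValueError(f"frame count {n} does not match meta.n_frames={self.meta.n_frames}")
        if r != self.meta.matrix_size or c != self.meta.matrix_size:
            raise ValueError(
                f"grid {r}x{c} does not match meta.matrix_size={self.meta.matrix_size}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    def with_counts(self, counts: np.ndarray) -> "DynamicRenogram":
        return replace(self, counts=counts)
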