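"""Mask post-processing and the automatic pie-shaped background ROI.

``clean_mask`` implements the kill-islands / fill-holes step applied to raw
network outputs.  ``auto_background_roi`` constructs a perirenal annular
sector at the 5 o'clock (right kidney) or 7 o'clock (left kidney) direction
when no background mask was produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import RoiSet, Side

__all__ = ["BackgroundRoiConfig", "clean_mask", "auto_background_roi", "needs_fallback", "EmptyBackgroundError"]


class EmptyBackgroundError(ValueError):
    """The constructed background ROI contained no pixels."""


@dataclass(frozen=True)
class BackgroundRoiConfig:
    gap_px: float = 2.0  # clearance between kidney and background ring
    annulus_width_px: float = 3.0
    clock_right: float = 5.0  # hour hand, right kidney sector
    clock_left: float = 7.0
    half_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.gap_px < 1:
            raise ValueError("gap_px must be >= 1 (background sits 1-2 px off the kidney)")
        if not (0 < self.half_angle_deg <= 90):
            raise ValueError("half_angle_deg must be in (0, 90]")


def clean_mask(raw: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected component and fill its interior holes.

    Empty input returns an empty mask.  Ties on component size are broken by
    the smallest top-left (row-major) pixel index, for determinism.
    """
    mask = np.asarray(raw, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size)
    if len(candidates) > 1:
        first_index = {
            lab: int(np.flatnonzero(labels.ravel() == lab)[0]) for lab in candidates
        }
        keep = min(candidates, key=lambda lab: first_index[lab])
    else:
        keep = candidates[0]
    out = labels == keep
    return ndimage.binary_fill_holes(out)


def clock_angle_deg(dr: float, dc: float) -> float:
    """Angle of (row-offset, col-offset) clockwise from image-up, in [0, 360)."""
    return float(np.degrees(np.arctan2(dc, -dr)) % 360.0)


def _angdiff(a: np.ndarray, b: float) -> np.ndarray:
    d = (a - b + 180.0) % 360.0 - 180.0
    return np.abs(d)


def auto_background_roi(
    kidney: np.ndarray,
    side: Side,
    config: BackgroundRoiConfig = BackgroundRoiConfig(),
    grid: int | None = None,
) -> np.ndarray:
    """Pie-shaped perirenal background: an annulus at Euclidean distance in
    (gap, gap+width] from the kidney, restricted to the clock-hour sector
    around the kidney centroid (hour h -> 30h degrees clockwise from up).
    """
    kidney = np.asarray(kidney, dtype=bool)
    if not kidney.any():
        raise ValueError("kidney mask empty")
    if grid is not None and kidney.shape != (grid, grid):
        raise ValueError(f"kidney mask shape {kidney.shape} != grid {grid}")

    dist = ndimage.distance_transform_edt(~kidney)
    ring = (dist > config.gap_px) & (dist <= config.gap_px + config.annulus_width_px)

    rc, cc = ndimage.center_of_mass(kidney)
    rows, cols = np.indices(kidney.shape)
    theta = np.degrees(np.arctan2(cols - cc, -(rows - rc))) % 360.0
    hour = config.clock_right if side == "right" else config.clock_left
    sector = _angdiff(theta, 30.0 * hour) <= config.half_angle_deg

    out = ring & sector
    if not out.any():
        raise EmptyBackgroundError(
            f"auto background for {side} kidney is empty (kidney at image edge?); "
            "consider widening the sector"
        )
    return out


def needs_fallback(predicted: RoiSet) -> dict[Side, bool]:
    """True per side when the cleaned background mask is empty."""
    return {
        "left": not clean_mask(predicted.bg_left).any(),
        "right": not clean_mask(predicted.bg_right).any(),
    }
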