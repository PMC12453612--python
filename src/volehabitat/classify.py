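"""RGB pixel classification of drone orthomosaics.

Dandelion flower heads are detected with a fixed yellow rule on normalized
reflectance (R > 0.9, G > 0.9, B < 0.1, strict); earth mounds with a brown
window calibrated per image from user-marked bare-earth training pixels,
because soil colour shifts with humidity.  Flower heads are counted from
yellow area at 7 cm^2 per head; buttercup distractors are dropped with a
connected-component size filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .scene import RGBScene

__all__ = [
    "PixelMask",
    "BrownWindow",
    "classify_yellow",
    "calibrate_brown_window",
    "classify_brown",
    "filter_small_components",
    "count_flower_heads",
    "extract_mound_points",
]

FLOWER_HEAD_CM2 = 7.0  # nominal area of one dandelion flower head


@dataclass
class PixelMask:
    """Binary raster aligned with its source scene."""

    values: np.ndarray  # bool, (rows, cols)
    label: str  # "yellow" | "brown"
    resolution: float
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area_m2(self) -> float:
        return float(self.values.sum()) * self.resolution**2


@dataclass
class BrownWindow:
    """Per-band closed reflectance intervals for bare earth."""

    r_min: float
    r_max: float
    g_min: float
    g_max: float
    b_min: float
    b_max: float

    def __post_init__(self) -> None:
        for lo, hi in ((self.r_min, self.r_max), (self.g_min, self.g_max), (self.b_min, self.b_max)):
            if lo > hi:
                raise ValueError("brown window requires min <= max per band")

    @property
    def width(self) -> float:
        return max(self.r_max - self.r_min, self.g_max - self.g_min, self.b_max - self.b_min)


def _check_scaled(pixels: np.ndarray) -> None:
    if pixels.min() < 0.0 or pixels.max() > 1.0:
        raise ValueError("bands must be scaled to [0, 1] (divide 8-bit input by 255)")


def classify_yellow(scene: RGBScene) -> PixelMask:
    """Yellow (dandelion) rule: R > 0.9 and G > 0.9 and B < 0.1, all strict."""
    px = scene.pixels
    _check_scaled(px)
    mask = (px[..., 0] > 0.9) & (px[..., 1] > 0.9) & (px[..., 2] < 0.1)
    return PixelMask(mask, "yellow", scene.resolution, {"rule": "R>0.9 & G>0.9 & B<0.1"})


def calibrate_brown_window(
    scene: RGBScene,
    training_points: pd.DataFrame | np.ndarray,
    q_low: float = 1.0,
    q_high: float = 99.0,
) -> BrownWindow:
    """Per-image brown calibration from marked bare-earth points.

    ``training_points`` carries metre coordinates (``x_m``, ``y_m`` columns or
    an (n, 2) array); the window is the per-band [q_low, q_high] percentile
    envelope of the sampled pixels.  A window wider than 0.5 in any band is
    flagged with a warning (training pixels probably span disjoint colours).
    """
    if isinstance(training_points, pd.DataFrame):
        xy = training_points[["x_m", "y_m"]].to_numpy()
    else:
        xy = np.asarray(training_points, dtype=float)
    if len(xy) == 0:
        raise ValueError("brown calibration needs at least one training pixel")
    if len(xy) < 10:
        warnings.warn("fewer than 10 brown training pixels; window may be unstable", stacklevel=2)
    h, w = scene.shape
    cols = np.clip((xy[:, 0] / scene.resolution).astype(int), 0, w - 1)
    rows = np.clip((h - xy[:, 1] / scene.resolution).astype(int), 0, h - 1)
    samples = scene.pixels[rows, cols]  # (n, 3)
    lo = np.percentile(samples, q_low, axis=0)
    hi = np.percentile(samples, q_high, axis=0)
    win = BrownWindow(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])
    if win.width > 0.5:
        warnings.warn("brown window is very wide; check the training pixels", stacklevel=2)
    return win


def classify_brown(scene: RGBScene, window: BrownWindow) -> PixelMask:
    """Brown (earth mound) mask: all three bands inside their closed intervals."""
    px = scene.pixels
    mask = (
        (px[..., 0] >= window.r_min)
        & (px[..., 0] <= window.r_max)
        & (px[..., 1] >= window.g_min)
        & (px[..., 1] <= window.g_max)
        & (px[..., 2] >= window.b_min)
        & (px[..., 2] <= window.b_max)
    )
    return PixelMask(mask, "brown", scene.resolution, {"window": window})


def filter_small_components(mask: PixelMask, min_pixels: int = 4) -> PixelMask:
    """Drop 4-connected components smaller than ``min_pixels``.

    The default of 4 pixels (~4 cm^2 at 1 cm/px) removes buttercup dots while
    keeping ~7-pixel dandelion discs.  ``min_pixels = 1`` is the identity.
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    if min_pixels == 1:
        return PixelMask(mask.values.copy(), mask.label, mask.resolution, mask.provenance)
    lab, n = measure.label(mask.values, connectivity=1, return_num=True)
    if n == 0:
        return PixelMask(np.zeros_like(mask.values), mask.label, mask.resolution, mask.provenance)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_pixels
    keep[0] = False
    return PixelMask(keep[lab], mask.label, mask.resolution, mask.provenance)


def count_flower_heads(mask: PixelMask, resolution: float | None = None) -> float:
    """Flower heads from yellow area: (pixels * pixel area in cm^2) / 7.

    The fractional value is preserved; rounding is the caller's choice.
    """
    res = mask.resolution if resolution is None else resolution
    if res <= 0:
        raise ValueError("resolution must be positive")
    area_cm2 = float(mask.values.sum()) * (res * 100.0) ** 2
    return area_cm2 / FLOWER_HEAD_CM2


def extract_mound_points(mask: PixelMask) -> pd.DataFrame:
    """One point per 4-connected brown component at its area centroid.

    Returns columns ``x_m, y_m, area_m2`` in quadrat coordinates (origin at
    the SW corner).  Component areas partition the total brown area.
    """
    lab, n = measure.label(mask.values, connectivity=1, return_num=True)
    if n == 0:
        return pd.DataFrame({"x_m": [], "y_m": [], "area_m2": []})
    props = measure.regionprops(lab)
    h = mask.values.shape[0]
    res = mask.resolution
    rows = np.array([p.centroid[0] for p in props])
    cols = np.array([p.centroid[1] for p in props])
    areas = np.array([p.area for p in props], dtype=float) * res**2
    return pd.DataFrame(
        {
            "x_m": (cols + 0.5) * res,
            "y_m": (h - rows - 0.5) * res,
            "area_m2": areas,
        }
    )
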