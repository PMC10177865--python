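"""Scratch-assay quantification: cell-free area, gap closure, t_closure, nu_a.

The cell-free gap is detected from texture, not intensity: a confluent cell
lawn is strongly textured while the scratched gap is smooth.  A local-
variance filter (default 10 px window) followed by Otsu thresholding of the
log-variance map separates the two; the largest connected low-variance
region is taken as the gap.  Because the variance window straddles the gap
boundary, the detected region is eroded by roughly half a window per side;
it is therefore dilated by ``window // 2`` before the area count.

Downstream quantities follow the standard wound-healing definitions:

* gap closure [%] at time t:  ``(1 - area_t / area_0) * 100`` (0 % at t0),
* t_closure: first time the closure curve reaches a level (default 100 %),
  linearly interpolated between flanking frames, censored if never reached,
* apparent velocity nu_a [%/h]: ``100 / t_closure`` when the gap closes,
  otherwise the least-squares slope of the closure curve (flagged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk, remove_small_objects

from .errors import ValidationError

log = logging.getLogger(__name__)

#: minimum ratio of lawn to gap local variance for a frame to count as
#: bimodal; unimodal frames are classified wholesale by texture contrast.
VARIANCE_RATIO_MIN = 10.0
#: median(local sd)/median(intensity) below this means "smooth" frame
SMOOTH_CONTRAST_MAX = 0.05


@dataclass(frozen=True)
class WoundFrame:
    frame: int
    time_h: float
    cell_free_area_px2: float


@dataclass
class VelocityEstimate:
    value_pct_per_h: float
    method: str  # "closure_time" | "slope"

    @property
    def slope_based(self) -> bool:
        return self.method == "slope"


def local_variance(image: np.ndarray, window_px: int) -> np.ndarray:
    """Windowed variance via uniform filters (E[x^2] - E[x]^2)."""
    img = np.asarray(image, float)
    mean = ndi.uniform_filter(img, window_px)
    mean_sq = ndi.uniform_filter(img * img, window_px)
    return np.maximum(mean_sq - mean * mean, 0.0)


def cell_free_area(
    image: np.ndarray,
    texture_window_px: int = 10,
    area_threshold_px2: int = 64,
) -> float:
    """Area (px^2) of the largest smooth (cell-free) region of one frame.

    ``area_threshold_px2`` removes speckle-sized low-variance islands before
    the largest component is extracted.  A frame without a clear smooth/
    textured bimodality is classified wholesale: all cell-free if its
    overall texture contrast is below 5 %, fully confluent (area 0)
    otherwise.
    """
    img = np.asarray(image, float)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("expected a non-empty single-channel image")
    if texture_window_px < 2 or texture_window_px > min(img.shape):
        raise ValidationError("texture window must be >= 2 and fit inside the image")

    var = local_variance(img, texture_window_px)
    log_var = np.log(np.maximum(var, 1e-9))
    contrast = float(np.median(np.sqrt(var)) / max(np.median(img), 1e-9))
    if log_var.max() - log_var.min() < 1e-6:
        return float(img.size) if contrast < SMOOTH_CONTRAST_MAX else 0.0
    thr = threshold_otsu(log_var)
    low = log_var < thr
    if not low.any() or low.all():
        return float(img.size) if contrast < SMOOTH_CONTRAST_MAX else 0.0
    ratio = var[~low].mean() / max(var[low].mean(), 1e-12)
    if ratio < VARIANCE_RATIO_MIN:
        # unimodal texture: the whole frame is either lawn or gap
        return float(img.size) if contrast < SMOOTH_CONTRAST_MAX else 0.0

    low = ndi.binary_fill_holes(low)
    low = remove_small_objects(low, max_size=max(area_threshold_px2 - 1, 0))
    labels, n = ndi.label(low)
    if n == 0:
        return 0.0
    sizes = np.bincount(labels.ravel())[1:]
    largest = labels == (int(np.argmax(sizes)) + 1)
    # compensate the half-window erosion at the lawn/gap boundary
    largest = ndi.binary_dilation(largest, structure=disk(texture_window_px // 2))
    return float(largest.sum())


def gap_closure(area_t: float, area_0: float) -> float:
    """Percentage gap closure ``(1 - area_t/area_0) * 100``.

    Negative values (gap widening) are returned as-is but logged.
    """
    if area_0 <= 0:
        raise ValidationError("baseline cell-free area must be positive")
    if area_t < 0:
        raise ValidationError("cell-free area must be >= 0")
    value = (1.0 - area_t / area_0) * 100.0
    if value < 0:
        log.warning("gap widened: closure %.2f%% < 0", value)
    return value


@dataclass
class WoundSeries:
    """Time-stamped cell-free areas and the derived closure curve."""

    times_h: np.ndarray
    areas_px2: np.ndarray

    def __init__(self, times_h: Sequence[float], areas_px2: Sequence[float]):
        t = np.asarray(times_h, float)
        a = np.asarray(areas_px2, float)
        if t.size != a.size or t.size < 1:
            raise ValidationError("times and areas must be equal-length, non-empty")
        if t[0] != 0:
            raise ValidationError("first frame must be at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(a < 0):
            raise ValidationError("areas must be >= 0")
        if a[0] <= 0:
            raise ValidationError("baseline cell-free area must be positive")
        self.times_h = t
        self.areas_px2 = a

    @property
    def gap_closure_pct(self) -> np.ndarray:
        return np.array([gap_closure(a, self.areas_px2[0]) for a in self.areas_px2])

    def time_to_closure(self, closure_level: float = 100.0) -> float | None:
        return time_to_closure(self.times_h, self.gap_closure_pct, closure_level)

    def apparent_velocity(self) -> VelocityEstimate:
        return apparent_velocity(self.times_h, self.gap_closure_pct)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times_h,
                "area_px2": self.areas_px2,
                "gap_closure_pct": self.gap_closure_pct,
            }
        )

    def summary(self) -> pd.DataFrame:
        t_close = self.time_to_closure()
        vel = self.apparent_velocity()
        return pd.DataFrame(
            [
                {
                    "t_closure_h": np.nan if t_close is None else t_close,
                    "censored": t_close is None,
                    "nu_a_pct_per_h": vel.value_pct_per_h,
                    "estimator_flag": vel.method,
                }
            ]
        )


def time_to_closure(
    times_h: Sequence[float],
    closure_pct: Sequence[float],
    closure_level: float = 100.0,
) -> float | None:
    """First time the closure curve reaches ``closure_level``; None if censored.

    Linear interpolation between the flanking frames; an exact frame hit
    returns that frame's time.
    """
    t = np.asarray(times_h, float)
    c = np.asarray(closure_pct, float)
    if t.size != c.size or t.size < 2:
        raise ValidationError("need >= 2 frames")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    for i in range(t.size):
        if c[i] >= closure_level:
            if i == 0 or c[i] == closure_level:
                return float(t[i])
            frac = (closure_level - c[i - 1]) / (c[i] - c[i - 1])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None


def apparent_velocity(
    times_h: Sequence[float], closure_pct: Sequence[float]
) -> VelocityEstimate:
    """nu_a = 100 / t_closure if closed, else least-squares slope (flagged)."""
    t = np.asarray(times_h, float)
    c = np.asarray(closure_pct, float)
    if t.size < 2:
        raise ValidationError("need >= 2 frames")
    t_close = time_to_closure(t, c)
    if t_close is not None:
        if t_close == 0:
            raise ValidationError("gap closed at t = 0; velocity undefined")
        return VelocityEstimate(100.0 / t_close, "closure_time")
    slope = float(np.polyfit(t, c, 1)[0])
    return VelocityEstimate(slope, "slope")


def series_from_images(
    images: Sequence[np.ndarray],
    times_h: Sequence[float],
    texture_window_px: int = 10,
    area_threshold_px2: int = 64,
) -> WoundSeries:
    """Detect cell-free areas across a frame sequence."""
    areas = [cell_free_area(im, texture_window_px, area_threshold_px2) for im in images]
    return WoundSeries(times_h, areas)


def average_replicates(frames: pd.DataFrame) -> pd.DataFrame:
    """Average cell-free areas over replicate images per timepoint.

    Expects columns ``time_h`` and ``area_px2`` (several pictures per gap
    per timepoint are averaged at the area level before gap closure).
    """
    if not {"time_h", "area_px2"}.issubset(frames.columns):
        raise ValidationError("expected columns time_h, area_px2")
    return (
        frames.groupby("time_h", as_index=False)["area_px2"].mean().sort_values("time_h")
    )
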