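"""Segmentation and shape-factor measurement for nuclei and cell bodies.

Two dimensionless shape factors characterize the epithelial-to-mesenchymal
axis of a cell:

* nuclear circularity ``C_N = 4*pi*A / P**2`` — 1 for a perfect circle,
  decreasing towards 0 for ellipsoid nuclei;
* cellular aspect ratio ``A_R = d_min / d_max`` of the fitted (moment-
  equivalent) ellipse — close to 1 for cobblestone-like epithelial cells,
  close to 0 for spindle-shaped mesenchymal cells.

Perimeters are estimated sub-pixel: marching-squares contour length on a
Gaussian-smoothed (sigma = 1 px) copy of the binary mask.  Raw pixel-edge or
raw marching-squares lengths overestimate circle perimeters by 5-20 % and
would bias circularity well below 1; the smoothed contour is within ~0.5 %
of the analytic value for radii >= 10 px.  The convention is fixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .errors import DegenerateObjectError, ValidationError

log = logging.getLogger(__name__)

MIN_MEASURABLE_AREA_PX = 5


@dataclass
class ObjectMask:
    """Labelled segmentation of one channel."""

    labels: np.ndarray  # int array, 0 = background
    channel: str  # "nucleus" | "cell"
    border_touching: dict[int, bool] = field(default_factory=dict)

    @property
    def object_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


@dataclass
class ShapeRecord:
    """Morphometry of a single segmented object."""

    object_id: int
    channel: str
    area_px2: float
    perimeter_px: float
    d_min_px: float
    d_max_px: float
    c_n: float
    a_r: float
    border_touching: bool = False
    c_n_clipped: bool = False


@dataclass
class ShapeSummary:
    """Per-condition mean +/- SD of the two shape factors."""

    condition: str
    n: int
    cn_mean: float
    cn_sd: float
    ar_mean: float
    ar_sd: float


def circularity(area: float, perimeter: float) -> float:
    """``4*pi*A / P**2``, clipped to at most 1.0 (digitization overshoot).

    A clip event is logged at WARNING level; analytic inputs never clip.
    """
    if area <= 0 or perimeter <= 0:
        raise ValidationError("area and perimeter must be positive")
    value = 4.0 * math.pi * area / perimeter**2
    if value > 1.0:
        log.warning("circularity %.4f > 1 clipped to 1.0", value)
        return 1.0
    return value


def aspect_ratio(d_min: float, d_max: float) -> float:
    """Minor over major fitted-ellipse axis, in (0, 1]."""
    if d_min <= 0 or d_max <= 0:
        raise ValidationError("axes must be positive")
    if d_min > d_max:
        raise ValidationError(f"d_min ({d_min}) exceeds d_max ({d_max})")
    return d_min / d_max


def segment_objects(
    image: np.ndarray,
    channel: str = "nucleus",
    min_area_px: int = 50,
    smoothing_sigma: float = 1.0,
    split_touching: bool | None = None,
) -> ObjectMask:
    """Global Otsu threshold -> connected components -> size filter.

    The nucleus channel additionally splits touching objects by watershed on
    the distance transform.  A contrast guard rejects blank noise-only
    images (Otsu on pure noise would otherwise label half the frame):
    foreground and background class means must differ by more than four
    background standard deviations.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("expected a non-empty single-channel image")
    if np.any(img < 0):
        raise ValidationError("image intensities must be non-negative")
    if channel not in ("nucleus", "cell"):
        raise ValidationError(f"unknown channel {channel!r}")

    smoothed = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    if smoothed.max() == smoothed.min():
        return ObjectMask(np.zeros_like(img, dtype=np.int32), channel)
    thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any() or fg.all():
        return ObjectMask(np.zeros_like(img, dtype=np.int32), channel)
    bg_sd = smoothed[~fg].std()
    if smoothed[fg].mean() - smoothed[~fg].mean() <= 4.0 * max(bg_sd, 1e-12):
        return ObjectMask(np.zeros_like(img, dtype=np.int32), channel)

    if split_touching is None:
        split_touching = channel == "nucleus"
    if split_touching:
        fg = remove_small_objects(fg, max_size=max(min_area_px - 1, 0))
        dist = ndi.distance_transform_edt(fg)
        # smooth the ridge of elongated objects so each yields one peak
        smooth_dist = ndi.gaussian_filter(dist, 2.0)
        peaks = peak_local_max(
            smooth_dist, labels=label(fg, connectivity=2), min_distance=12,
            exclude_border=False,
        )
        markers = np.zeros_like(fg, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        markers = ndi.grey_dilation(markers, size=3)
        labels = watershed(-dist, markers=markers, mask=fg)
    else:
        labels = label(fg, connectivity=2)

    # drop objects under the size floor, then relabel contiguously
    sizes = np.bincount(labels.ravel())
    too_small = np.flatnonzero(sizes < min_area_px)
    labels[np.isin(labels, too_small)] = 0
    labels = label(labels > 0, connectivity=2) if not split_touching else _relabel(labels)

    border = np.zeros(labels.max() + 1, bool)
    for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        border[np.unique(edge)] = True
    touching = {int(i): bool(border[i]) for i in np.unique(labels) if i != 0}
    return ObjectMask(labels.astype(np.int32), channel, touching)


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids != 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[labels]


def contour_perimeter(mask: np.ndarray, smoothing_sigma: float = 1.0) -> float:
    """Sub-pixel perimeter: marching squares on a smoothed binary mask."""
    padded = np.pad(mask.astype(float), 3)
    if smoothing_sigma > 0:
        padded = ndi.gaussian_filter(padded, smoothing_sigma)
    contours = find_contours(padded, 0.5)
    if not contours:
        return 0.0
    longest = max(contours, key=len)
    steps = np.diff(longest, axis=0)
    return float(np.sqrt((steps**2).sum(axis=1)).sum())


def measure_object(mask: ObjectMask, object_id: int, image: np.ndarray | None = None) -> ShapeRecord:
    """Area, sub-pixel perimeter, fitted-ellipse axes and shape factors.

    ``d_min``/``d_max`` are the full minor/major axes of the moment-
    equivalent ellipse (the objective stand-in for manually drawn axes).
    """
    binary = mask.labels == object_id
    if object_id <= 0 or not binary.any():
        raise LookupError(f"object id {object_id} not present in mask")
    area = int(binary.sum())
    if area < MIN_MEASURABLE_AREA_PX:
        raise DegenerateObjectError(f"object {object_id} has only {area} px")

    perimeter = contour_perimeter(binary)
    props = regionprops(binary.astype(np.uint8))[0]
    d_max = float(props.axis_major_length)
    d_min = float(props.axis_minor_length)
    if d_min <= 0:  # single-row/column object: fall back to 1 px width
        d_min = 1.0
    raw_cn = 4.0 * math.pi * area / perimeter**2 if perimeter > 0 else 0.0
    return ShapeRecord(
        object_id=object_id,
        channel=mask.channel,
        area_px2=float(area),
        perimeter_px=perimeter,
        d_min_px=d_min,
        d_max_px=d_max,
        c_n=circularity(area, perimeter) if perimeter > 0 else float("nan"),
        a_r=aspect_ratio(d_min, d_max),
        border_touching=mask.border_touching.get(object_id, False),
        c_n_clipped=raw_cn > 1.0,
    )


def measure_all(mask: ObjectMask, exclude_border: bool = True) -> list[ShapeRecord]:
    """Measure every labelled object, optionally skipping border-touchers."""
    records = []
    for oid in mask.object_ids:
        if exclude_border and mask.border_touching.get(oid, False):
            continue
        try:
            records.append(measure_object(mask, oid))
        except DegenerateObjectError:
            log.info("skipping degenerate object %d", oid)
    return records


def summarize_shapes(records: Sequence[ShapeRecord], condition: str) -> ShapeSummary:
    """Sample mean and SD (n-1 denominator) of C_N and A_R."""
    records = [r for r in records if not r.border_touching]
    if not records:
        raise ValidationError("no records to summarize")
    cn = np.array([r.c_n for r in records], float)
    ar = np.array([r.a_r for r in records], float)
    n = len(records)
    return ShapeSummary(
        condition=condition,
        n=n,
        cn_mean=float(cn.mean()),
        cn_sd=float(cn.std(ddof=1)) if n > 1 else 0.0,
        ar_mean=float(ar.mean()),
        ar_sd=float(ar.std(ddof=1)) if n > 1 else 0.0,
    )


def records_to_frame(records: Iterable[ShapeRecord], image_name: str = "") -> pd.DataFrame:
    """Tidy per-object table matching the documented CSV layout."""
    return pd.DataFrame(
        [
            {
                "image": image_name,
                "object_id": r.object_id,
                "channel": r.channel,
                "area_px2": r.area_px2,
                "perimeter_px": r.perimeter_px,
                "d_min_px": r.d_min_px,
                "d_max_px": r.d_max_px,
                "c_n": r.c_n,
                "a_r": r.a_r,
                "border_flag": r.border_touching,
            }
            for r in records
        ]
    )
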