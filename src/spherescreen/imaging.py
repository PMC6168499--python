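"""Spheroid segmentation and the two health readouts.

The screen quantifies spheroid health from per-well image crops with two
dimensionless numbers:

* shape factor  S_F = P^2 / (4*pi*A)  — 1 for a circle, rising as the
  boundary roughens when a spheroid disaggregates;
* viable fraction  V_F = Area_FDA / Area_BF_pre-drug  — end-point FDA
  (live stain) area relative to the brightfield area measured on the last
  day before drug incubation; V_F >= 1 means grown/unaffected, < 1 a
  detrimental effect.

Perimeters are measured on a sub-pixel contour (marching squares at the
0.5 level of a lightly smoothed mask): pixel-edge counting would
overestimate a circle's perimeter by up to ~27 % and destroy the S_F ~ 1
reference point for healthy spheroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .layout import DeviceLayout
from .synth import SyntheticImageSet, polygon_area, polygon_perimeter

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "segment_spheroid",
    "shape_factor",
    "viable_fraction",
    "classify_viability",
    "measure_timecourse",
    "exclude_edge_columns",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Settings for the threshold-based spheroid segmentation.

    ``invert`` selects dark-object-on-bright-background images
    (brightfield); fluorescence channels keep the default polarity.
    ``smoothing_sigma_px`` smooths the binary mask before the sub-pixel
    contour is traced, suppressing single-pixel staircase artefacts.
    """

    threshold_method: str = "otsu"  # otsu | fixed
    fixed_threshold: float | None = None
    min_object_area_um2: float = 300.0
    fill_holes: bool = True
    smoothing_sigma_px: float = 1.0
    opening_radius_px: int = 2
    invert: bool = False

    def __post_init__(self) -> None:
        if self.min_object_area_um2 < 0:
            raise ValueError("minimum object area cannot be negative")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold method needs fixed_threshold")


@dataclass
class SegmentationResult:
    mask: np.ndarray | None
    contour_px: np.ndarray | None  # (N, 2) sub-pixel (x, y) polygon
    area_um2: float | None
    perimeter_um: float | None
    no_detection: bool = False
    multi_object: bool = False


def _subpixel_contour(mask: np.ndarray, sigma: float) -> np.ndarray | None:
    """Longest marching-squares contour of the mask at the 0.5 level."""
    f = mask.astype(float)
    if sigma > 0:
        f = ndimage.gaussian_filter(f, sigma)
    contours = measure.find_contours(f, 0.5)
    if not contours:
        return None
    longest = max(contours, key=len)
    # find_contours yields (row, col); convert to (x, y)
    return longest[:, ::-1]


def segment_spheroid(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_scale_um: float = 1.0,
) -> SegmentationResult:
    """Segment the single spheroid in a well crop.

    Global threshold (Otsu by default), hole filling, then the largest
    connected component above the minimum area; the measurement contour is
    traced at sub-pixel precision on the retained mask.  If several
    components pass the area cut the largest is kept and ``multi_object``
    is set; if none passes, ``no_detection`` is set and no measurement is
    produced.
    """
    params = params or SegmentationParams()
    img = np.asarray(image, dtype=float)
    work = -img if params.invert else img
    if params.threshold_method == "otsu":
        thr = filters.threshold_otsu(work)
    else:
        thr = -params.fixed_threshold if params.invert else params.fixed_threshold
    mask = work > thr
    if params.opening_radius_px > 0:
        # opening removes threshold speckle (Otsu always splits, even pure
        # noise) while leaving solid spheroid-sized objects intact
        mask = ndimage.binary_opening(mask, iterations=params.opening_radius_px)
    if params.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        return SegmentationResult(None, None, None, None, no_detection=True)
    min_px = params.min_object_area_um2 / pixel_scale_um**2
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.where(sizes >= min_px)[0]
    if keep.size == 0:
        return SegmentationResult(None, None, None, None, no_detection=True)
    best = keep[np.argmax(sizes[keep])] + 1
    obj = labels == best
    contour = _subpixel_contour(obj, params.smoothing_sigma_px)
    if contour is None or len(contour) < 8:
        return SegmentationResult(None, None, None, None, no_detection=True)
    area = polygon_area(contour) * pixel_scale_um**2
    perim = polygon_perimeter(contour) * pixel_scale_um
    return SegmentationResult(
        mask=obj,
        contour_px=contour,
        area_um2=float(area),
        perimeter_um=float(perim),
        multi_object=keep.size > 1,
    )


def shape_factor(contour_or_mask: np.ndarray, smoothing_sigma_px: float = 1.0) -> float:
    """S_F = P^2/(4*pi*A) from a closed contour or a binary mask.

    Accepts an (N, 2) polygon (N >= 8) or a 2D boolean mask, in which case
    the sub-pixel boundary is traced first.  Dimensionless and scale
    invariant; 1 for an ideal circle by the isoperimetric equality.
    """
    arr = np.asarray(contour_or_mask)
    if arr.ndim == 2 and arr.shape[1] == 2 and arr.dtype != bool:
        contour = arr
    elif arr.ndim == 2:
        c = _subpixel_contour(arr.astype(bool), smoothing_sigma_px)
        if c is None:
            raise ValueError("no boundary found in mask")
        contour = c
    else:
        raise ValueError("expected an (N, 2) contour or a 2D mask")
    if len(contour) < 8:
        raise ValueError("contour needs at least 8 vertices")
    area = polygon_area(contour)
    if area <= 0:
        raise ValueError("degenerate contour with zero area")
    return polygon_perimeter(contour) ** 2 / (4.0 * math.pi * area)


def viable_fraction(area_fda_um2: float, baseline_area_um2: float) -> float:
    """V_F = Area_FDA / Area_BF_PtD (baseline = pre-drug brightfield area)."""
    if baseline_area_um2 is None or not baseline_area_um2 > 0:
        raise ValueError("viable fraction needs a positive pre-drug baseline area")
    if area_fda_um2 < 0:
        raise ValueError("FDA area cannot be negative")
    return area_fda_um2 / baseline_area_um2


def classify_viability(v_f: float) -> str:
    """Spheroids with V_F >= 1 grew or were unaffected; < 1 is detrimental."""
    return "grown_or_unaffected" if v_f >= 1.0 else "detrimental"


def measure_timecourse(
    image_set: SyntheticImageSet,
    layout: DeviceLayout | None = None,
    params: SegmentationParams | None = None,
    drug_day: int | None = None,
) -> pd.DataFrame:
    """Measure every well on every imaging day.

    Returns one row per (well, day) with area, perimeter, equivalent
    diameter, shape factor, and — on days with FDA frames — the FDA area
    and viable fraction computed against the pre-drug baseline area (the
    last brightfield frame before ``drug_day``).  Missing or undetected
    wells are flagged rather than fatal.
    """
    layout = layout or image_set.layout
    drug_day = image_set.drug_day if drug_day is None else drug_day
    if params is None:
        params = SegmentationParams(invert=True)  # brightfield polarity
    fluor_params = SegmentationParams(
        threshold_method=params.threshold_method,
        fixed_threshold=params.fixed_threshold,
        min_object_area_um2=params.min_object_area_um2,
        fill_holes=params.fill_holes,
        smoothing_sigma_px=params.smoothing_sigma_px,
        opening_radius_px=params.opening_radius_px,
        invert=False,
    )
    scale = image_set.pixel_scale_um
    days = sorted(image_set.days)
    baseline_days = [d for d in days if d < drug_day]
    if not baseline_days:
        raise ValueError("no imaging day precedes drug application; baseline undefined")
    baseline_day = max(baseline_days)

    rows = []
    for row in range(1, layout.n_rows + 1):
        for col in range(1, layout.n_cols + 1):
            baseline_area = None
            per_day = {}
            for day in days:
                key = (row, col, day, "brightfield")
                if key not in image_set.images:
                    per_day[day] = None
                    continue
                seg = segment_spheroid(image_set.images[key], params, scale)
                per_day[day] = seg
                if day == baseline_day and not seg.no_detection:
                    baseline_area = seg.area_um2
            for day in days:
                seg = per_day[day]
                flags = []
                rec = {
                    "well_row": row,
                    "well_col": col,
                    "day": day,
                    "area_um2": np.nan,
                    "perimeter_um": np.nan,
                    "eq_diam_um": np.nan,
                    "shape_factor": np.nan,
                    "fda_area_um2": np.nan,
                    "baseline_area_um2": baseline_area if baseline_area else np.nan,
                    "viable_fraction": np.nan,
                }
                if seg is None:
                    flags.append("missing_frame")
                elif seg.no_detection:
                    flags.append("no_detection")
                else:
                    if seg.multi_object:
                        flags.append("multi_object")
                    rec["area_um2"] = seg.area_um2
                    rec["perimeter_um"] = seg.perimeter_um
                    rec["eq_diam_um"] = 2.0 * math.sqrt(seg.area_um2 / math.pi)
                    rec["shape_factor"] = seg.perimeter_um**2 / (4.0 * math.pi * seg.area_um2)
                fda_key = (row, col, day, "fda")
                if fda_key in image_set.images:
                    fseg = segment_spheroid(image_set.images[fda_key], fluor_params, scale)
                    fda_area = 0.0 if fseg.no_detection else fseg.area_um2
                    rec["fda_area_um2"] = fda_area
                    if baseline_area:
                        rec["viable_fraction"] = viable_fraction(fda_area, baseline_area)
                    else:
                        flags.append("no_baseline")
                rec["flags"] = ";".join(flags)
                rows.append(rec)
    return pd.DataFrame(rows)


def exclude_edge_columns(
    table: pd.DataFrame, layout: DeviceLayout, k: int = 3
) -> pd.DataFrame:
    """Drop wells in the first and last ``k`` columns of the array.

    Wells there see fringe effects of the concentration gradient, so their
    doses are less certain and they are excluded from analysis views.
    """
    if k < 0:
        raise ValueError("k cannot be negative")
    if 2 * k >= layout.n_cols:
        raise ValueError(f"excluding {k} columns per side empties a {layout.n_cols}-column array")
    if k == 0:
        return table.copy()
    keep = (table["well_col"] > k) & (table["well_col"] <= layout.n_cols - k)
    return table[keep].reset_index(drop=True)
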