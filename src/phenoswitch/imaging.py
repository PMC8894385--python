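"""Segmentation and per-cell morphometrics.

Cells are segmented from two-channel fluorescence images by
nucleus-seeded watershed: nuclei (channel 0) provide one seed per cell,
cell bodies (channel 1) provide the foreground mask, and a watershed on
the inverted body intensity splits touching cells at their ridge.

Two dimensionless shape descriptors drive phenotype classification:

* elongation  E  = major axis / minor axis of the moment-matched
  ellipse (≥ 1; large for spindle-shaped contractile cells);
* cell shape index  CSI = 4π·area / perimeter²  (1 for a circle,
  → 0 for elongated shapes; clamped to ≤ 1 because discrete perimeter
  estimators can slightly undershoot on digitized circles).

Classification bounds (strict inequalities; boundary values fall
through to ``unclassified``):

* contractile:  E > 3  and  CSI < 0.4
* synthetic:    1 < E < 3  and  CSI > 0.6
* undecided:    0.4 < CSI < 0.6
* unclassified: everything else, including shape combinations the
  three classes do not cover and degenerate objects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu, threshold_yen
from skimage.measure import label as cc_label
from skimage.measure import regionprops_table
from skimage.morphology import remove_small_holes, remove_small_objects
from skimage.segmentation import clear_border, watershed

__all__ = [
    "ClassThresholds",
    "SegmentationParams",
    "csi",
    "segment_cells",
    "measure_shape",
    "classify_phenotype",
    "classify_records",
]

PHENOTYPES = ("contractile", "synthetic", "undecided", "unclassified")


@dataclass(frozen=True)
class ClassThresholds:
    """Published decision bounds on the (E, CSI) plane."""

    e_contractile_min: float = 3.0
    csi_contractile_max: float = 0.4
    e_synthetic_min: float = 1.0
    e_synthetic_max: float = 3.0
    csi_synthetic_min: float = 0.6
    csi_undecided: tuple[float, float] = (0.4, 0.6)

    def __post_init__(self) -> None:
        lo, hi = self.csi_undecided
        if not (self.csi_contractile_max <= lo < hi <= self.csi_synthetic_min):
            raise ValueError("CSI intervals must be ordered and non-overlapping")
        if not (self.e_synthetic_min < self.e_synthetic_max):
            raise ValueError("E interval for synthetic must be non-degenerate")


@dataclass(frozen=True)
class SegmentationParams:
    nucleus_threshold_method: str = "otsu"
    min_cell_area: float = 40.0
    max_cell_area: float = 20_000.0
    border_exclusion: bool = True
    smoothing_sigma: float = 1.0
    min_nucleus_area: float = 8.0
    # reject thresholds that merely split noise: foreground/background
    # mean separation must exceed this many background SDs
    min_contrast_snr: float = 4.0
    # re-threshold each cell at this fraction of its own peak intensity;
    # a global threshold places the boundary at a fixed intensity, which
    # systematically dilates bright cells and biases E low on thin cells
    halfmax_fraction: float | None = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_cell_area < self.max_cell_area:
            raise ValueError("require 0 < min_cell_area < max_cell_area")


def csi(area: float, perimeter: float) -> float:
    """Cell shape index 4π·area/perimeter², clamped to ≤ 1."""
    if perimeter <= 0:
        return float("nan")
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def _threshold_mask(
    channel: np.ndarray, method: str, snr: float
) -> np.ndarray:
    """Threshold one smoothed channel, returning an all-False mask when the
    image has no real foreground (blank / noise-only wells)."""
    if method == "otsu":
        thr = threshold_otsu(channel)
    elif method == "yen":
        thr = threshold_yen(channel)
    else:
        raise ValueError(f"unknown threshold method: {method!r}")
    mask = channel > thr
    frac = mask.mean()
    if frac == 0.0 or frac > 0.5:
        return np.zeros_like(mask)
    bg = channel[~mask]
    sep = channel[mask].mean() - bg.mean()
    if bg.std() > 0 and sep < snr * bg.std():
        return np.zeros_like(mask)
    return mask


def _refine_halfmax(
    labels: np.ndarray, body: np.ndarray, fraction: float
) -> np.ndarray:
    """Re-threshold each labeled cell at ``fraction`` of its own peak
    intensity (above background) within its watershed territory.

    For a blurred step edge the half-maximum contour sits on the true
    object boundary, so this removes the per-cell dilation/erosion a
    single global threshold causes on cells of unequal brightness.
    """
    out = np.zeros_like(labels)
    bg = float(np.median(body[labels == 0])) if (labels == 0).any() else 0.0
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region = labels[sl] == lab
        vals = body[sl]
        peak = np.percentile(vals[region], 95)
        keep = region & (vals > bg + fraction * (peak - bg))
        out[sl][keep] = lab
    return out


def segment_cells(
    image: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Nucleus-seeded watershed segmentation of a (2, H, W) image.

    Returns an int32 label image; 0 is background.  A well with no
    detectable nuclei yields an all-zero mask with a warning.
    """
    params = params or SegmentationParams()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("expected a two-channel image of shape (2, H, W)")
    for c in range(2):
        if np.ptp(image[c]) == 0:
            raise ValueError(f"channel {c} is constant")

    sig = params.smoothing_sigma
    nuc = ndimage.gaussian_filter(image[0].astype(np.float64), sig)
    body = ndimage.gaussian_filter(image[1].astype(np.float64), sig)

    nuc_mask = _threshold_mask(
        nuc, params.nucleus_threshold_method, params.min_contrast_snr
    )
    nuc_mask = remove_small_objects(
        nuc_mask, max_size=int(params.min_nucleus_area)
    )
    seeds = cc_label(nuc_mask)
    if seeds.max() == 0:
        warnings.warn("no nuclei detected; returning empty mask", stacklevel=2)
        return np.zeros(image.shape[1:], dtype=np.int32)

    body_mask = _threshold_mask(
        body, params.nucleus_threshold_method, params.min_contrast_snr
    )
    if params.halfmax_fraction is not None and body_mask.any():
        # grow the watershed territory down to the noise floor so the
        # per-cell half-max step, not the global threshold, decides the
        # boundary of dim cells
        bg_px = body[~body_mask]
        floor = np.median(bg_px) + 4.0 * 1.4826 * np.median(
            np.abs(bg_px - np.median(bg_px))
        )
        body_mask = body > floor
    body_mask = remove_small_holes(body_mask | nuc_mask, max_size=64)
    labels = watershed(-body, markers=seeds, mask=body_mask)

    if params.halfmax_fraction is not None:
        labels = _refine_halfmax(labels, body, params.halfmax_fraction)

    if params.border_exclusion:
        labels = clear_border(labels)
    if labels.max() > 0:
        areas = np.bincount(labels.ravel())
        bad = np.flatnonzero(
            (areas < params.min_cell_area) | (areas > params.max_cell_area)
        )
        labels[np.isin(labels, bad[bad > 0])] = 0
    # relabel to consecutive positive integers
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def measure_shape(
    mask: np.ndarray,
    well_id: str = "well",
) -> pd.DataFrame:
    """Per-label morphometrics from a labeled mask.

    Columns: well_id, label, area (px²), perimeter (px, Crofton
    estimator), major_axis, minor_axis (px, from the ellipse with
    matching normalized second central moments), elongation_E, csi,
    centroid x/y, degenerate flag.  Degenerate objects (vanishing minor
    axis or perimeter) are kept but flagged; they classify as
    ``unclassified`` downstream.
    """
    mask = np.asarray(mask)
    if mask.max() == 0:
        return pd.DataFrame(
            columns=[
                "well_id", "label", "area", "perimeter", "major_axis",
                "minor_axis", "elongation_E", "csi", "x", "y", "degenerate",
            ]
        )
    props = regionprops_table(
        mask.astype(np.int32),
        properties=(
            "label", "area", "perimeter_crofton", "moments_central",
            "centroid",
        ),
    )
    df = pd.DataFrame(props).rename(
        columns={
            "perimeter_crofton": "perimeter",
            "centroid-0": "y",
            "centroid-1": "x",
        }
    )
    # axis lengths from the ellipse with matching second central moments;
    # pixels are unit squares, so each contributes 1/12 within-pixel
    # variance on top of its center coordinate (point-mass moments bias
    # the minor axis of thin objects low)
    area = df["area"].to_numpy(dtype=float)
    var_r = df["moments_central-2-0"].to_numpy() / area
    var_c = df["moments_central-0-2"].to_numpy() / area
    cov_rc = df["moments_central-1-1"].to_numpy() / area
    mean_v = (var_r + var_c) / 2.0
    half_span = np.sqrt(((var_r - var_c) / 2.0) ** 2 + cov_rc**2)
    lam2_point = mean_v - half_span  # point-mass minor eigenvalue
    lam1 = mean_v + half_span + 1.0 / 12.0
    lam2 = lam2_point + 1.0 / 12.0
    df["major_axis"] = 4.0 * np.sqrt(lam1)
    df["minor_axis"] = 4.0 * np.sqrt(lam2)
    df = df.drop(columns=[c for c in df.columns if c.startswith("moments_")])
    degenerate = (lam2_point <= 1e-12) | (df["perimeter"] <= 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate object(s) flagged",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        e = df["major_axis"] / df["minor_axis"]
        c = np.minimum(
            1.0, 4.0 * math.pi * df["area"] / df["perimeter"] ** 2
        )
    df["elongation_E"] = np.where(degenerate, np.nan, np.maximum(1.0, e))
    df["csi"] = np.where(degenerate, np.nan, c)
    df["degenerate"] = degenerate
    df.insert(0, "well_id", well_id)
    return df


def classify_phenotype(
    elongation_e: float, csi_value: float,
    thresholds: ClassThresholds | None = None,
) -> str:
    """Assign exactly one phenotype label from (E, CSI).

    All inequalities are strict; NaN metrics give ``unclassified`` (with
    a warning), as do shape combinations the class definitions do not
    cover (e.g. highly elongated but round-looking E > 3, CSI > 0.6).
    """
    t = thresholds or ClassThresholds()
    if not (np.isfinite(elongation_e) and np.isfinite(csi_value)):
        warnings.warn("NaN/inf shape metric → unclassified", stacklevel=2)
        return "unclassified"
    if elongation_e > t.e_contractile_min and csi_value < t.csi_contractile_max:
        return "contractile"
    if (
        t.e_synthetic_min < elongation_e < t.e_synthetic_max
        and csi_value > t.csi_synthetic_min
    ):
        return "synthetic"
    lo, hi = t.csi_undecided
    if lo < csi_value < hi:
        return "undecided"
    return "unclassified"


def classify_records(
    records: pd.DataFrame,
    thresholds: ClassThresholds | None = None,
    e_col: str = "elongation_E",
    csi_col: str = "csi",
) -> pd.DataFrame:
    """Vectorized classification: adds a ``phenotype`` column."""
    t = thresholds or ClassThresholds()
    e = records[e_col].to_numpy(dtype=float)
    c = records[csi_col].to_numpy(dtype=float)
    out = np.full(len(records), "unclassified", dtype=object)
    finite = np.isfinite(e) & np.isfinite(c)
    lo, hi = t.csi_undecided
    und = finite & (lo < c) & (c < hi)
    con = finite & (e > t.e_contractile_min) & (c < t.csi_contractile_max)
    syn = (
        finite
        & (t.e_synthetic_min < e)
        & (e < t.e_synthetic_max)
        & (c > t.csi_synthetic_min)
    )
    out[und] = "undecided"
    out[syn] = "synthetic"
    out[con] = "contractile"
    result = records.copy()
    result["phenotype"] = out
    return result
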