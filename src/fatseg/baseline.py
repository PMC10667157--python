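"""Automated histogram-threshold baseline for SAT/VAT segmentation.

This is an automated analogue of the semiautomated reference method:
construct a body mask, choose an intensity threshold on the region's
histogram to classify fat, and split the fat into a subcutaneous ring
(connected to the body boundary) and visceral depots (inside the
abdominal cavity). Reader supervision is replaced by Otsu threshold
selection with an optional manual override, so the module is a baseline,
not a reproduction of the interactive reference procedure.

Because fat-bright organs (kidneys, bowel) overlap the fat intensity
tail, pure thresholding misclassifies parts of them as visceral fat; the
same regional misclassification affects intensity-based reference methods
on real abdominal MR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .io import BACKGROUND, SAT, VAT

__all__ = ["ThresholdConfig", "body_mask", "split_rois", "threshold_fat", "segment_slice"]


@dataclass(frozen=True)
class ThresholdConfig:
    """Baseline parameters. Radii are in millimetres and are converted to
    pixels with the slice's pixel spacing."""

    body_threshold_quantile: float = 0.5
    closing_radius_mm: float = 5.0
    erosion_radius_mm: float = 4.0
    histogram_bins: int = 64
    threshold_method: str = "otsu"
    manual_threshold_override: float | None = None

    def __post_init__(self) -> None:
        if self.closing_radius_mm < 0 or self.erosion_radius_mm < 0:
            raise ValueError("morphology radii must be non-negative")
        if self.histogram_bins < 16:
            raise ValueError(f"histogram_bins must be >= 16, got {self.histogram_bins}")
        if self.threshold_method not in ("otsu", "valley"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if not 0 < self.body_threshold_quantile < 1:
            raise ValueError("body_threshold_quantile must be in (0, 1)")


def _radius_px(radius_mm: float, pixel_spacing_mm: float) -> int:
    return max(int(round(radius_mm / pixel_spacing_mm)), 1)


def body_mask(image: np.ndarray, config: ThresholdConfig, pixel_spacing_mm: float = 1.0) -> np.ndarray:
    """Largest connected above-background component, closed and hole-filled."""
    image = np.asarray(image, dtype=float)
    if image.max() <= 0:
        warnings.warn("blank image: empty body mask", stacklevel=2)
        return np.zeros(image.shape, dtype=bool)
    # background air is near zero; threshold at a quantile of the nonzero mass
    thr = np.quantile(image[image > 0], config.body_threshold_quantile) * 0.25
    fg = image > thr
    fg = ndimage.binary_closing(fg, structure=disk(_radius_px(config.closing_radius_mm, pixel_spacing_mm)))
    labels, n = ndimage.label(fg)
    if n == 0:
        warnings.warn("no foreground component found: empty body mask", stacklevel=2)
        return np.zeros(image.shape, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def threshold_fat(image: np.ndarray, roi: np.ndarray, config: ThresholdConfig) -> np.ndarray:
    """Binary fat mask within an ROI via histogram threshold selection.

    Otsu's criterion on the ROI histogram by default; a manual override
    value, when given, is used verbatim (emulating reader adjustment).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    vals = np.asarray(image, dtype=float)[roi]
    if config.manual_threshold_override is not None:
        thr = config.manual_threshold_override
    elif np.ptp(vals) == 0:
        thr = vals[0]  # degenerate flat ROI: nothing above threshold
    elif config.threshold_method == "otsu":
        # Otsu's criterion has a plateau of optima between well-separated
        # modes; intermeans iteration settles on the class-mean midpoint
        thr = threshold_otsu(vals, nbins=config.histogram_bins)
        for _ in range(64):
            lo, hi = vals[vals <= thr], vals[vals > thr]
            if lo.size == 0 or hi.size == 0:
                break
            new = (lo.mean() + hi.mean()) / 2.0
            if abs(new - thr) < 1e-9:
                break
            thr = new
    else:  # valley: lowest histogram bin between the two outer modes
        hist, edges = np.histogram(vals, bins=config.histogram_bins)
        centers = (edges[:-1] + edges[1:]) / 2
        modes = np.argsort(hist)[::-1]
        lo_mode, hi_mode = sorted((int(modes[0]), int(np.max(modes[:8]))))
        if lo_mode == hi_mode:
            thr = float(centers[lo_mode])
        else:
            valley = lo_mode + int(np.argmin(hist[lo_mode:hi_mode + 1]))
            thr = float(centers[valley])
    out = np.zeros(np.shape(image), dtype=bool)
    out[roi] = np.asarray(image, dtype=float)[roi] > thr
    return out


def split_rois(
    body: np.ndarray,
    fat_candidates: np.ndarray,
    config: ThresholdConfig,
    pixel_spacing_mm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split fat candidates into the subcutaneous ring and the visceral ROI.

    SAT is every fat component connected to the body boundary ring; the
    visceral ROI is the body interior minus the SAT ring and a safety
    margin along its inner contour. The two ROIs are disjoint on every
    input.
    """
    body = np.asarray(body, dtype=bool)
    fat_candidates = np.asarray(fat_candidates, dtype=bool) & body
    if not body.any():
        raise ValueError("no body mask")
    r = _radius_px(config.erosion_radius_mm, pixel_spacing_mm)
    boundary_ring = body & ~ndimage.binary_erosion(body, structure=disk(r))
    labels, n = ndimage.label(fat_candidates)
    touching = np.unique(labels[boundary_ring & (labels > 0)])
    sat_roi = np.isin(labels, touching) & fat_candidates if touching.size else np.zeros_like(body)
    interior = ndimage.binary_erosion(body & ~sat_roi, structure=disk(r))
    vat_roi = interior & ~sat_roi
    return sat_roi, vat_roi & ~sat_roi


def segment_slice(
    image: np.ndarray, config: ThresholdConfig | None = None, pixel_spacing_mm: float = 1.0
) -> np.ndarray:
    """End-to-end baseline segmentation of one slice into {0, 1, 2}."""
    config = config or ThresholdConfig()
    image = np.asarray(image, dtype=float)
    body = body_mask(image, config, pixel_spacing_mm)
    out = np.zeros(image.shape, dtype=np.uint8)
    if not body.any():
        return out
    fat = threshold_fat(image, body, config)
    sat_roi, vat_roi = split_rois(body, fat, config, pixel_spacing_mm)
    out[sat_roi] = SAT
    out[fat & vat_roi] = VAT
    return out
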