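"""Slice-to-volume fat quantification.

Per-slice label maps are converted to physical SAT/VAT/TAT volumes by
multiplying per-slice class areas by the through-plane extent of one
slice. By default that extent is thickness + gap (the interslice gap is
attributed to the slice's sample volume, giving contiguous abdominal
coverage); a gap-exclusive mode is available via ``include_gap=False``.

Predictions made on the model grid (e.g. 256 x 256) are resampled to the
native acquisition grid with nearest-neighbour interpolation before areas
are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SAT, VAT, LABELS, SeriesGeometry

__all__ = ["FatVolumes", "mask_area", "series_volume", "quantify_subject", "resample_labels"]


@dataclass(frozen=True)
class FatVolumes:
    """Per-subject fat volumes in liters plus the VAT/SAT ratio.

    Invariants: all volumes >= 0; tat_l == sat_l + vat_l exactly;
    vat_sat_ratio is 0 when sat_l == 0.
    """

    sat_l: float
    vat_l: float
    tat_l: float
    vat_sat_ratio: float
    sat_areas_cm2: tuple[float, ...] = field(default=(), repr=False)
    vat_areas_cm2: tuple[float, ...] = field(default=(), repr=False)


def mask_area(mask: np.ndarray, label: int, pixel_spacing_mm: tuple[float, float]) -> float:
    """Area in cm^2 covered by ``label`` in a 2-D label map."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label}; expected one of {LABELS}")
    sr, sc = pixel_spacing_mm
    if sr <= 0 or sc <= 0:
        raise ValueError(f"pixel spacing must be positive, got {(sr, sc)}")
    return float(np.count_nonzero(np.asarray(mask) == label) * sr * sc / 100.0)


def series_volume(areas_cm2, geometry: SeriesGeometry, include_gap: bool = True) -> float:
    """Integrate per-slice areas (cm^2) into a volume in liters.

    volume_l = sum(area_cm2) * extent_mm / 10 / 1000, where extent is
    thickness + gap (default) or thickness alone.
    """
    areas = np.asarray(areas_cm2, dtype=float)
    if areas.size != geometry.n_slices:
        raise ValueError(f"{areas.size} areas for {geometry.n_slices} slices")
    extent_mm = geometry.slice_pitch_mm if include_gap else geometry.slice_thickness_mm
    return float(np.sum(areas) * (extent_mm / 10.0) / 1000.0)


def resample_labels(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resample of a 2-D label map to ``shape``."""
    mask = np.asarray(mask)
    if mask.shape == tuple(shape):
        return mask
    rows = (np.arange(shape[0]) + 0.5) * mask.shape[0] / shape[0] - 0.5
    cols = (np.arange(shape[1]) + 0.5) * mask.shape[1] / shape[1] - 0.5
    ri = np.clip(np.rint(rows).astype(int), 0, mask.shape[0] - 1)
    ci = np.clip(np.rint(cols).astype(int), 0, mask.shape[1] - 1)
    return mask[np.ix_(ri, ci)]


def quantify_subject(
    masks: np.ndarray, geometry: SeriesGeometry, include_gap: bool = True
) -> FatVolumes:
    """Convert a (n_slices, H, W) label-map stack into :class:`FatVolumes`.

    Masks on a grid other than the native acquisition matrix are
    resampled (nearest neighbour) to ``geometry.matrix`` first.
    """
    masks = np.asarray(masks)
    if masks.ndim != 3 or masks.shape[0] != geometry.n_slices:
        raise ValueError(
            f"expected ({geometry.n_slices}, H, W) mask stack, got {masks.shape}"
        )
    if masks.shape[1:] != geometry.matrix:
        masks = np.stack([resample_labels(m, geometry.matrix) for m in masks])
    sat_areas = tuple(mask_area(m, SAT, geometry.pixel_spacing_mm) for m in masks)
    vat_areas = tuple(mask_area(m, VAT, geometry.pixel_spacing_mm) for m in masks)
    sat_l = series_volume(sat_areas, geometry, include_gap)
    vat_l = series_volume(vat_areas, geometry, include_gap)
    return FatVolumes(
        sat_l=sat_l,
        vat_l=vat_l,
        tat_l=sat_l + vat_l,
        vat_sat_ratio=vat_l / sat_l if sat_l > 0 else 0.0,
        sat_areas_cm2=sat_areas,
        vat_areas_cm2=vat_areas,
    )
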