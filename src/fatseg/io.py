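"""Reading and writing of imaging artifacts: NIfTI volumes, DICOM series,
label maps and dataset manifests.

The canonical on-disk format is NIfTI-1; DICOM is read-only ingest. Label
semantics are fixed globally: 0 = background, 1 = subcutaneous adipose
tissue (SAT), 2 = visceral adipose tissue (VAT). The through-plane pitch of
an axial series is stored as slice thickness plus interslice gap; both are
retained separately (the NIfTI affine carries the pitch, the header
``descrip`` field carries the split).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

LABELS = (0, 1, 2)
BACKGROUND, SAT, VAT = LABELS

#: slice positions in a DICOM series may jitter by at most this much (mm)
SPACING_TOL_MM = 0.01


@dataclass(frozen=True)
class SeriesGeometry:
    """Physical geometry of an axial MR series.

    Parameters
    ----------
    pixel_spacing_mm
        In-plane spacing as ``(row, col)`` in millimetres.
    slice_thickness_mm
        Excited slab thickness of each slice.
    interslice_gap_mm
        Unimaged tissue between consecutive slices; together with the
        thickness it defines the through-plane pitch.
    n_slices
        Number of axial slices.
    matrix
        In-plane matrix as ``(rows, cols)``.
    """

    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    interslice_gap_mm: float
    n_slices: int
    matrix: tuple[int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError(f"pixel_spacing_mm must be positive, got {self.pixel_spacing_mm}")
        if self.slice_thickness_mm <= 0:
            raise ValueError(f"slice_thickness_mm must be positive, got {self.slice_thickness_mm}")
        if self.interslice_gap_mm < 0:
            raise ValueError(f"interslice_gap_mm must be non-negative, got {self.interslice_gap_mm}")
        if self.n_slices < 1:
            raise ValueError(f"n_slices must be >= 1, got {self.n_slices}")
        if any(m < 1 for m in self.matrix):
            raise ValueError(f"matrix dims must be >= 1, got {self.matrix}")

    @property
    def slice_pitch_mm(self) -> float:
        """Through-plane distance between consecutive slice centres."""
        return self.slice_thickness_mm + self.interslice_gap_mm

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1]


@dataclass
class MRSeries:
    """An axial MR series: image stack(s) of shape (n_slices, rows, cols)."""

    in_phase: np.ndarray
    geometry: SeriesGeometry
    opposed_phase: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        expect = (self.geometry.n_slices, *self.geometry.matrix)
        if self.in_phase.shape != expect:
            raise ValueError(f"in_phase shape {self.in_phase.shape} != geometry {expect}")
        if self.opposed_phase is not None and self.opposed_phase.shape != expect:
            raise ValueError(f"opposed_phase shape {self.opposed_phase.shape} != geometry {expect}")


def _affine(geometry: SeriesGeometry) -> np.ndarray:
    sr, sc = geometry.pixel_spacing_mm
    return np.diag([float(sc), float(sr), geometry.slice_pitch_mm, 1.0])


def _descrip(geometry: SeriesGeometry) -> bytes:
    return f"thk={geometry.slice_thickness_mm:g};gap={geometry.interslice_gap_mm:g}".encode()


def _parse_descrip(hdr, pitch: float) -> tuple[float, float]:
    m = re.match(rb"thk=([0-9.eE+-]+);gap=([0-9.eE+-]+)", bytes(hdr["descrip"]))
    if m:
        return float(m.group(1)), float(m.group(2))
    # foreign NIfTI: treat the whole pitch as thickness
    return pitch, 0.0


def write_series(series: MRSeries, path: str | Path) -> None:
    """Write an MR series as NIfTI (in-phase channel; rows, cols, slices on disk)."""
    path = Path(path)
    data = np.asarray(series.in_phase, dtype=np.float32).transpose(2, 1, 0)
    img = nib.Nifti1Image(data, _affine(series.geometry))
    img.header["descrip"] = _descrip(series.geometry)
    nib.save(img, path)


def read_series(path: str | Path) -> MRSeries:
    """Read an MR series from a NIfTI file or a DICOM directory.

    DICOM slices are sorted by slice position; the interslice gap is
    inferred as the inter-slice position delta minus the slice thickness.
    Inconsistent slice spacing (beyond 0.01 mm) is a hard error.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0)
    zooms = img.header.get_zooms()
    pitch = float(zooms[2])
    thk, gap = _parse_descrip(img.header, pitch)
    geometry = SeriesGeometry(
        pixel_spacing_mm=(float(zooms[1]), float(zooms[0])),
        slice_thickness_mm=thk,
        interslice_gap_mm=gap,
        n_slices=data.shape[0],
        matrix=(data.shape[1], data.shape[2]),
    )
    return MRSeries(in_phase=data, geometry=geometry, subject_id=path.stem.split(".")[0])


def _read_dicom_dir(path: Path) -> MRSeries:
    files = sorted(p for p in path.iterdir() if p.is_file())
    dsets = []
    for f in files:
        try:
            dsets.append(pydicom.dcmread(f))
        except pydicom.errors.InvalidDicomError:
            continue
    if not dsets:
        raise FileNotFoundError(f"no DICOM files under {path}")
    dsets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    positions = np.array([float(d.ImagePositionPatient[2]) for d in dsets])
    thickness = float(dsets[0].SliceThickness)
    spacing = tuple(float(s) for s in dsets[0].PixelSpacing)
    if len(dsets) > 1:
        deltas = np.diff(positions)
        if np.ptp(deltas) > SPACING_TOL_MM:
            raise ValueError(
                f"inconsistent slice spacing in {path}: deltas range "
                f"[{deltas.min():.4f}, {deltas.max():.4f}] mm exceeds {SPACING_TOL_MM} mm tolerance"
            )
        gap = float(np.mean(deltas)) - thickness
    else:
        gap = 0.0
    stack = np.stack([d.pixel_array.astype(np.float32) for d in dsets])
    geometry = SeriesGeometry(
        pixel_spacing_mm=spacing,
        slice_thickness_mm=thickness,
        interslice_gap_mm=max(gap, 0.0),
        n_slices=len(dsets),
        matrix=stack.shape[1:],
    )
    return MRSeries(in_phase=stack, geometry=geometry, subject_id=path.name)


def write_labelmap(mask: np.ndarray, geometry: SeriesGeometry, path: str | Path) -> None:
    """Write a (stack of) label map(s) as integer NIfTI. Labels must be in {0,1,2}."""
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError(f"label map must have integer dtype, got {mask.dtype}")
    if not np.isin(mask, LABELS).all():
        bad = np.setdiff1d(np.unique(mask), LABELS)
        raise ValueError(f"label map contains values outside {LABELS}: {bad}")
    data = mask.astype(np.uint8)
    if data.ndim == 2:
        data = data[None]
    img = nib.Nifti1Image(data.transpose(2, 1, 0), _affine(geometry))
    img.header["descrip"] = _descrip(geometry)
    nib.save(img, Path(path))


def read_labelmap(path: str | Path) -> tuple[np.ndarray, SeriesGeometry]:
    """Read a label map written by :func:`write_labelmap`; lossless for labels."""
    series = read_series(path)
    mask = series.in_phase.astype(np.uint8)
    if not np.isin(mask, LABELS).all():
        raise ValueError(f"file {path} contains labels outside {LABELS}")
    return mask, series.geometry


MANIFEST_COLUMNS = ["subject_id", "image_path", "label_path", "fold_id", "true_sat_l", "true_vat_l"]


def save_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    """Save a dataset manifest as CSV (paths stored relative to the CSV)."""
    _check_manifest(manifest)
    manifest.reindex(columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load a dataset manifest; subject ids must be unique and paths must exist."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    _check_manifest(df)
    root = path.parent
    for col in ("image_path", "label_path"):
        if col in df.columns:
            for p in df[col].dropna():
                if not (root / p).exists() and not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")
    return df


def _check_manifest(df: pd.DataFrame) -> None:
    if "subject_id" not in df.columns:
        raise ValueError("manifest must have a subject_id column")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id values in manifest: {sorted(set(dup))}")


def resolve_path(manifest_path: str | Path, p: str) -> Path:
    """Resolve a manifest-relative path."""
    cand = Path(manifest_path).parent / p
    return cand if cand.exists() else Path(p)
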