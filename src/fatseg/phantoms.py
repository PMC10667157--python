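"""Seeded synthetic abdominal MR phantoms with exact SAT/VAT ground truth.

Each phantom subject emulates a dual-echo gradient-echo axial abdominal
series: an elliptical body with smooth radial perturbation, a subcutaneous
fat (SAT) ring of angularly varying thickness directly under the skin, a
muscular wall, and an abdominal cavity containing soft-tissue confounder
organs (spine, kidney pair, bowel loops, bladder) plus randomly placed
visceral fat (VAT) ellipsoid depots. The in-phase channel is water + fat
signal and the opposed-phase channel |water - fat|, so fat is the
brightest tissue in-phase. Confounder organs are given signal means in the
upper tail of the intensity histogram so that pure intensity thresholding
misclassifies part of them as visceral fat, as happens with fat-bright
organs in real abdominal MR.

Anatomy varies smoothly along the craniocaudal axis (cross-sectional area
rises then falls); every geometric primitive is rasterised analytically,
so the ground-truth label map is exact before noise is applied. All
randomness is derived from (seed, subject index, blob index) counter-style
streams, so cohorts are extensible and adding VAT depots never reshuffles
existing ones.

Intensity units are arbitrary; normalisation happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import SAT, VAT, MRSeries, SeriesGeometry, save_manifest, write_labelmap, write_series
from .volumetry import FatVolumes, quantify_subject

__all__ = ["PhantomSpec", "PhantomSlice", "PhantomSubject", "generate_slice",
           "generate_subject", "generate_cohort", "subject_seed_for"]

DEFAULT_ORGAN_SIGNALS: Mapping[str, float] = {
    "spine": 0.50,
    "kidneys": 0.68,
    "bowel": 0.78,
    "bladder": 0.30,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic acquisition and anatomy.

    Geometry defaults follow a whole-abdominal fat-quantification
    protocol: 50 axial slices of 10 mm thickness with a 0.5 mm interslice
    gap, a 530 mm field of view reconstructed on a 480 x 480 matrix.
    Anatomy ranges target an obesity-range habitus. ``noise_sigma`` is the
    scale of Rician noise; ``bias_field_amplitude`` the relative amplitude
    of a smooth multiplicative shading field.
    """

    image_size: int = 480
    fov_mm: float = 530.0
    n_slices: int = 50
    slice_thickness_mm: float = 10.0
    interslice_gap_mm: float = 0.5
    body_axes_mm: tuple[tuple[float, float], tuple[float, float]] = ((165.0, 215.0), (115.0, 155.0))
    sat_thickness_mm: tuple[float, float] = (18.0, 45.0)
    wall_thickness_mm: float = 8.0
    vat_blob_count: tuple[int, int] = (16, 32)
    vat_blob_size_mm: tuple[float, float] = (16.0, 52.0)
    organ_set: tuple[str, ...] = ("spine", "kidneys", "bowel", "bladder")
    organ_signals: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ORGAN_SIGNALS))
    fat_signal: float = 1.0
    water_signal: float = 0.35
    noise_sigma: float = 0.04
    bias_field_amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("image_size", "fov_mm", "n_slices", "slice_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("interslice_gap_mm", "noise_sigma", "bias_field_amplitude", "wall_thickness_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        for name in ("sat_thickness_mm", "vat_blob_size_mm"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive well-ordered range, got {(lo, hi)}")
        lo, hi = self.vat_blob_count
        if not (0 <= lo <= hi):
            raise ValueError(f"vat_blob_count must be a well-ordered non-negative range, got {(lo, hi)}")
        (alo, ahi), (blo, bhi) = self.body_axes_mm
        if not (0 < alo <= ahi and 0 < blo <= bhi):
            raise ValueError(f"body_axes_mm ranges must be positive and well-ordered, got {self.body_axes_mm}")
        # SAT ring plus wall must leave a cavity inside the smallest body
        if self.sat_thickness_mm[1] + self.wall_thickness_mm >= blo * 0.8:
            raise ValueError(
                "sat_thickness_mm upper bound plus wall_thickness_mm leaves no abdominal cavity "
                f"inside the smallest body semi-axis {blo}"
            )
        unknown = set(self.organ_set) - set(self.organ_signals)
        if unknown:
            raise ValueError(f"organ_set entries without a signal mean: {sorted(unknown)}")

    @property
    def pixel_spacing_mm(self) -> float:
        return self.fov_mm / self.image_size

    def geometry(self) -> SeriesGeometry:
        s = self.pixel_spacing_mm
        return SeriesGeometry(
            pixel_spacing_mm=(s, s),
            slice_thickness_mm=self.slice_thickness_mm,
            interslice_gap_mm=self.interslice_gap_mm,
            n_slices=self.n_slices,
            matrix=(self.image_size, self.image_size),
        )


@dataclass
class PhantomSlice:
    in_phase: np.ndarray
    opposed_phase: np.ndarray
    truth: np.ndarray
    geometry: SeriesGeometry
    slice_index: int


@dataclass
class PhantomSubject:
    series: MRSeries
    truth: np.ndarray
    true_volumes: FatVolumes
    subject_seed: int


# ---------------------------------------------------------------------------
# subject-level anatomy parameters

@dataclass(frozen=True)
class _Anatomy:
    a: float                      # body semi-axis, left-right (mm)
    b: float                      # body semi-axis, anterior-posterior (mm)
    perturb: tuple[tuple[float, float], ...]   # (eps_k, phase_k) for k = 2..4
    sat_base: float               # SAT ring thickness, angular mean (mm)
    sat_amp: float                # angular modulation amplitude (mm)
    sat_phase: float
    n_blobs: int
    blobs: tuple[tuple[float, ...], ...]  # (rho, phi, ax, ay, ang, zc, ze) each
    bias_coeffs: tuple[float, ...]


def _subject_rng(spec: PhantomSpec, subject_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, subject_seed & 0x7FFFFFFF, *key]))


def _draw_anatomy(spec: PhantomSpec, subject_seed: int) -> _Anatomy:
    rng = _subject_rng(spec, subject_seed, 0)
    (alo, ahi), (blo, bhi) = spec.body_axes_mm
    a = rng.uniform(alo, ahi)
    b = rng.uniform(blo, bhi)
    perturb = tuple((rng.uniform(0.0, 0.04), rng.uniform(0, 2 * np.pi)) for _ in range(2, 5))
    tlo, thi = spec.sat_thickness_mm
    base = rng.uniform(tlo + 0.25 * (thi - tlo), thi - 0.25 * (thi - tlo)) if thi > tlo else tlo
    amp = min(rng.uniform(0.0, 0.5 * (thi - tlo)), base - tlo, thi - base) if thi > tlo else 0.0
    phase = rng.uniform(0, 2 * np.pi)
    n_blobs = int(rng.integers(spec.vat_blob_count[0], spec.vat_blob_count[1] + 1))
    # each depot drawn from its own stream so depot i is identical whatever n_blobs is
    blobs = []
    slo, shi = spec.vat_blob_size_mm
    for i in range(n_blobs):
        brng = _subject_rng(spec, subject_seed, 1, i)
        rho = np.sqrt(brng.uniform(0.0, 1.0)) * 0.85
        phi = brng.uniform(0, 2 * np.pi)
        ax = brng.uniform(slo, shi) / 2.0
        ay = brng.uniform(slo, shi) / 2.0
        ang = brng.uniform(0, np.pi)
        zc = brng.uniform(0.1, 0.9)
        ze = brng.uniform(0.15, 0.45)
        blobs.append((rho, phi, ax, ay, ang, zc, ze))
    bias = tuple(rng.uniform(-1.0, 1.0, size=6))
    return _Anatomy(a, b, perturb, base, amp, phase, n_blobs, tuple(blobs), bias)


def _z_scale(spec: PhantomSpec, slice_index: int) -> tuple[float, float]:
    """Craniocaudal profile: cross-sectional area rises then falls."""
    t = (slice_index + 0.5) / spec.n_slices
    return 0.75 + 0.25 * np.sin(np.pi * t) ** 0.8, t


def _grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    n = spec.image_size
    c = (n - 1) / 2.0
    coords = (np.arange(n) - c) * spec.pixel_spacing_mm
    y, x = np.meshgrid(coords, coords, indexing="ij")  # y: anterior->posterior (rows)
    return x, y


def _ellipse_mask(x, y, cx, cy, ax, ay, ang=0.0) -> np.ndarray:
    ca, sa = np.cos(ang), np.sin(ang)
    u = (x - cx) * ca + (y - cy) * sa
    v = -(x - cx) * sa + (y - cy) * ca
    return (u / ax) ** 2 + (v / ay) ** 2 < 1.0


def _analytic_masks(spec: PhantomSpec, anat: _Anatomy, slice_index: int):
    """Exact geometric masks for one slice: body, SAT ring, cavity, VAT, organs."""
    x, y = _grids(spec)
    s, t = _z_scale(spec, slice_index)
    a, b = anat.a * s, anat.b * s
    theta = np.arctan2(y, x)
    pert = np.ones_like(theta)
    for k, (eps, ph) in zip(range(2, 5), anat.perturb):
        pert += eps * np.cos(k * theta + ph)
    ao, bo = a * pert, b * pert                       # outer skin boundary (per-pixel)
    body = (x / ao) ** 2 + (y / bo) ** 2 < 1.0
    thick = anat.sat_base + anat.sat_amp * np.cos(theta - anat.sat_phase)
    ai, bi = np.maximum(ao - thick, 1.0), np.maximum(bo - thick, 1.0)
    inner = (x / ai) ** 2 + (y / bi) ** 2 < 1.0       # inside SAT ring
    sat = body & ~inner
    ac = np.maximum(ai - spec.wall_thickness_mm, 1.0)
    bc = np.maximum(bi - spec.wall_thickness_mm, 1.0)
    cavity = (x / ac) ** 2 + (y / bc) ** 2 < 1.0
    a_cav, b_cav = (a - anat.sat_base - spec.wall_thickness_mm), (b - anat.sat_base - spec.wall_thickness_mm)

    vat = np.zeros_like(body)
    for rho, phi, ax_, ay_, ang, zc, ze in anat.blobs:
        dz = (t - zc) / ze
        if abs(dz) >= 1.0:
            continue
        scale = np.sqrt(1.0 - dz * dz)               # ellipsoid cross-section
        cx = rho * a_cav * np.cos(phi)
        cy = rho * b_cav * np.sin(phi)
        vat |= _ellipse_mask(x, y, cx, cy, ax_ * scale, ay_ * scale, ang)
    vat &= cavity

    organs = {}
    def organ(name, mask, z_lo, z_hi):
        if name in spec.organ_set and z_lo <= t <= z_hi:
            organs[name] = mask & cavity
    organ("spine", _ellipse_mask(x, y, 0.0, 0.72 * b_cav, 20.0, 20.0), 0.0, 1.0)
    organ("kidneys",
          _ellipse_mask(x, y, -0.48 * a_cav, 0.38 * b_cav, 32.0, 19.0, 0.4)
          | _ellipse_mask(x, y, 0.48 * a_cav, 0.38 * b_cav, 32.0, 19.0, -0.4), 0.25, 0.65)
    organ("bowel",
          _ellipse_mask(x, y, -0.30 * a_cav, -0.35 * b_cav, 17.0, 13.0, 0.8)
          | _ellipse_mask(x, y, 0.22 * a_cav, -0.45 * b_cav, 15.0, 12.0, 2.1)
          | _ellipse_mask(x, y, 0.05 * a_cav, -0.05 * b_cav, 14.0, 11.0, 1.4), 0.15, 0.95)
    organ("bladder", _ellipse_mask(x, y, 0.0, 0.30 * b_cav, 28.0, 22.0), 0.82, 1.0)

    organ_union = np.zeros_like(body)
    for m in organs.values():
        organ_union |= m
    vat &= ~organ_union
    return body, sat, cavity, vat, organs


def _bias_field(spec: PhantomSpec, anat: _Anatomy) -> np.ndarray:
    if spec.bias_field_amplitude == 0:
        return np.ones((spec.image_size, spec.image_size))
    n = spec.image_size
    u = np.linspace(-1, 1, n)
    yy, xx = np.meshgrid(u, u, indexing="ij")
    c = anat.bias_coeffs
    f = c[0] * xx + c[1] * yy + c[2] * xx * yy + c[3] * xx**2 + c[4] * yy**2 + c[5]
    peak = np.max(np.abs(f))
    if peak > 0:
        f = f / peak
    return 1.0 + spec.bias_field_amplitude * f


def generate_slice(spec: PhantomSpec, slice_index: int, subject_seed: int) -> PhantomSlice:
    """Generate one axial phantom slice with exact ground truth.

    Deterministic for fixed ``(spec, slice_index, subject_seed)``. The
    truth label map is derived from the analytic geometry before noise and
    shading are applied.
    """
    if not 0 <= slice_index < spec.n_slices:
        raise ValueError(f"slice_index {slice_index} outside [0, {spec.n_slices})")
    anat = _draw_anatomy(spec, subject_seed)
    body, sat, cavity, vat, organs = _analytic_masks(spec, anat, slice_index)

    truth = np.zeros(body.shape, dtype=np.uint8)
    truth[sat] = SAT
    truth[vat] = VAT

    fat = np.where((truth == SAT) | (truth == VAT), spec.fat_signal, 0.0)
    water = np.where(body & (truth == 0), spec.water_signal, 0.0)
    for name, mask in organs.items():
        water[mask] = spec.organ_signals[name]
    water[fat > 0] = 0.0

    in_phase = (water + fat) * _bias_field(spec, anat)
    opposed = np.abs(water - fat) * _bias_field(spec, anat)

    if spec.noise_sigma > 0:
        rng = _subject_rng(spec, subject_seed, 2, slice_index)
        for img in (in_phase, opposed):
            n1 = rng.normal(0, spec.noise_sigma, img.shape)
            n2 = rng.normal(0, spec.noise_sigma, img.shape)
            img[:] = np.sqrt((img + n1) ** 2 + n2**2)

    return PhantomSlice(
        in_phase=in_phase.astype(np.float32),
        opposed_phase=opposed.astype(np.float32),
        truth=truth,
        geometry=spec.geometry(),
        slice_index=slice_index,
    )


def generate_subject(spec: PhantomSpec, subject_seed: int) -> PhantomSubject:
    """Generate a full axial series with aligned truth stack and recorded
    ground-truth volumes (computed from the truth masks, hence exactly
    consistent with downstream volumetry)."""
    slices = [generate_slice(spec, i, subject_seed) for i in range(spec.n_slices)]
    in_phase = np.stack([s.in_phase for s in slices])
    opposed = np.stack([s.opposed_phase for s in slices])
    truth = np.stack([s.truth for s in slices])
    geometry = spec.geometry()
    series = MRSeries(in_phase=in_phase, opposed_phase=opposed, geometry=geometry,
                      subject_id=f"S{subject_seed:08d}")
    return PhantomSubject(
        series=series,
        truth=truth,
        true_volumes=quantify_subject(truth, geometry),
        subject_seed=subject_seed,
    )


def subject_seed_for(cohort_seed: int, index: int) -> int:
    """Counter-based per-subject seed; stable under cohort extension."""
    return int(np.random.SeedSequence([cohort_seed & 0x7FFFFFFF, index]).generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(
    out_dir: str | Path, n_subjects: int, spec: PhantomSpec, seed: int
) -> pd.DataFrame:
    """Generate a cohort to disk: per-subject NIfTI image/label volumes and a
    CSV manifest with recorded ground-truth volumes."""
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_subjects):
        sseed = subject_seed_for(seed, i)
        subj = generate_subject(spec, sseed)
        sid = f"sub-{i:03d}"
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        image_path = sdir / "inphase.nii.gz"
        label_path = sdir / "labels.nii.gz"
        subj.series.subject_id = sid
        write_series(subj.series, image_path)
        write_labelmap(subj.truth, subj.series.geometry, label_path)
        rows.append({
            "subject_id": sid,
            "image_path": str(image_path.relative_to(out_dir)),
            "label_path": str(label_path.relative_to(out_dir)),
            "fold_id": None,
            "true_sat_l": subj.true_volumes.sat_l,
            "true_vat_l": subj.true_volumes.vat_l,
        })
    manifest = pd.DataFrame(rows)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
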