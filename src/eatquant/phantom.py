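"""Synthetic cardiac-CT phantom with analytically known EAT volume and attenuation.

The phantom emulates the geometry that matters to the quantification pipeline,
not scanner physics: an axial stack of HU-valued slices containing a body
ellipse (soft tissue), two lung ellipses (air-like), a heart disc, and — on a
contiguous block of slices — an epicardial-fat ring: a sector of the annulus
between the heart disc and a surrounding pericardium circle.  Ring radii vary
smoothly along z so per-slice areas differ, which exercises the trapezoidal
volume rule nontrivially.

Every labeled EAT voxel is clamped into the conventional adipose HU window
[−190, −30] after noise, the per-slice EAT areas are known in closed form, and
the ground-truth volume is computed from those parametric areas with the same
trapezoidal rule the quantifier uses — making the phantom an exact oracle for
the whole mask → volume/attenuation pathway.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .image_io import (
    BinaryMask,
    CTSeries,
    CTSlice,
    MaskSeries,
    write_ct_series,
    write_mask_series,
)

HU_FAT_WINDOW = (-190.0, -30.0)


class PhantomError(ValueError):
    """Raised for phantom specifications that cannot be rasterized."""


@dataclass
class EATGeometry:
    """Parametric fat-ring geometry, in pixels on the native grid.

    The ring is the sector (fraction ``sector_fraction`` of the full circle,
    starting at angle ``sector_start``) of the annulus between the heart disc
    of radius ``r_heart(j)`` and the pericardium circle of radius
    ``r_heart(j) + thickness(j)``.  Both radii follow a smooth axial profile:
    ``shape(u) = taper + (1 - taper) * sin(pi * u)`` with ``u`` the normalized
    position inside the EAT slice block, so areas peak mid-block and taper at
    the ends.
    """

    center: tuple[float, float] | None = None  # px; default slightly off-grid-center
    heart_radius: float | None = None  # px at the widest slice; default 0.165 * grid
    eat_thickness: float | None = None  # ring thickness at the widest slice; default 0.085 * grid
    sector_fraction: float = 0.8
    sector_start: float = 0.3  # radians
    taper: float = 0.45

    def resolve(self, grid_size: int) -> "EATGeometry":
        g = EATGeometry(**asdict(self))
        if g.center is None:
            # irrational offsets decorrelate circle boundaries from the lattice
            g.center = (grid_size / 2 + math.pi / 7, grid_size / 2 - math.e / 9)
        if g.heart_radius is None:
            g.heart_radius = 0.165 * grid_size
        if g.eat_thickness is None:
            g.eat_thickness = 0.085 * grid_size
        return g

    def profile(self, j: int, n_eat: int) -> float:
        u = (j + 0.5) / n_eat
        return self.taper + (1.0 - self.taper) * math.sin(math.pi * u)

    def radii(self, j: int, n_eat: int) -> tuple[float, float]:
        s = self.profile(j, n_eat)
        rh = self.heart_radius * s
        return rh, rh + self.eat_thickness * s

    def sector_area_px(self, j: int, n_eat: int) -> float:
        """Parametric ring cross-section on slice j, in squared pixels."""
        rh, rp = self.radii(j, n_eat)
        return self.sector_fraction * math.pi * (rp ** 2 - rh ** 2)


@dataclass
class PhantomSpec:
    """Full description of one synthetic patient.

    ``z_spacing`` may be a scalar (uniform gaps), a per-gap list, or ``None``
    to draw each gap uniformly from the 2.2–4.5 mm range seen in clinical
    acquisitions (deterministically from ``seed``).
    """

    n_slices: int = 12
    eat_slice_range: tuple[int, int] = (3, 8)  # inclusive
    grid_size: int = 512
    pixel_spacing: float = 0.7  # mm, sx == sy
    z_spacing: float | Sequence[float] | None = None
    eat_geometry: EATGeometry = field(default_factory=EATGeometry)
    eat_hu_mean: float = -90.0
    eat_hu_sd: float = 12.0
    background_hu_levels: dict = field(
        default_factory=lambda: {"air": -1000.0, "body": 40.0, "heart": 45.0, "lung": -800.0}
    )
    noise_sd: float = 5.0
    distractor_blobs: int = 0  # fat-like blobs outside the pericardium
    seed: int = 0
    patient_id: str = "phantom-000"

    def __post_init__(self) -> None:
        lo, hi = self.eat_slice_range
        if not (0 <= lo <= hi < self.n_slices):
            raise PhantomError(
                f"eat_slice_range {self.eat_slice_range} not inside [0, {self.n_slices})"
            )
        if not (HU_FAT_WINDOW[0] <= self.eat_hu_mean <= HU_FAT_WINDOW[1]):
            raise PhantomError(
                f"eat_hu_mean {self.eat_hu_mean} outside the fat window {HU_FAT_WINDOW}"
            )
        if self.pixel_spacing <= 0:
            raise PhantomError("pixel_spacing must be positive")
        geo = self.eat_geometry.resolve(self.grid_size)
        n_eat = hi - lo + 1
        for j in range(n_eat):
            rh, rp = geo.radii(j, n_eat)
            cx, cy = geo.center
            if (rp - rh) < 1.5:
                raise PhantomError(
                    f"EAT ring thinner than 1.5 px on slice {lo + j}; cannot rasterize reliably"
                )
            if cx - rp < 1 or cy - rp < 1 or cx + rp > self.grid_size - 1 or cy + rp > self.grid_size - 1:
                raise PhantomError("EAT region exceeds the image grid")
        gaps = self.resolved_z_gaps()
        if np.any(gaps <= 0):
            raise PhantomError("all z gaps must be strictly positive")

    @property
    def n_eat_slices(self) -> int:
        lo, hi = self.eat_slice_range
        return hi - lo + 1

    def resolved_z_gaps(self) -> np.ndarray:
        """The n_slices − 1 inter-slice gaps in mm (drawn from seed if unset)."""
        n = self.n_slices - 1
        if self.z_spacing is None:
            rng = np.random.default_rng([int(self.seed) % (2 ** 31), 17])
            return rng.uniform(2.2, 4.5, size=n)
        z = np.asarray(self.z_spacing, dtype=float)
        if z.ndim == 0:
            return np.full(n, float(z))
        if len(z) != n:
            raise PhantomError(f"need {n} z gaps, got {len(z)}")
        return z

    def z_positions(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.resolved_z_gaps())])


@dataclass
class GroundTruth:
    """Analytic per-patient truth for the quantification pathway."""

    eatv_ml: float
    eatd_hu: float
    per_slice_areas: np.ndarray  # mm^2, one entry per slice (0 off the EAT block)
    slice_labels: np.ndarray  # 0/1 per slice

    def __post_init__(self) -> None:
        self.per_slice_areas = np.asarray(self.per_slice_areas, dtype=float)
        self.slice_labels = np.asarray(self.slice_labels, dtype=int)
        if (self.eatv_ml > 0) != bool(self.slice_labels.any()):
            raise PhantomError("eatv_ml > 0 must coincide with at least one positive label")


def analytic_ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Closed-form EATv / EATd for a phantom spec, without rasterizing.

    The volume applies the same trapezoidal rule as the quantifier to the
    parametric per-slice areas of the EAT-bearing block, so the two pathways
    differ only by rasterization.  The mean attenuation is the noiseless EAT
    value (noise is zero-mean, so recovery error scales as noise_sd / sqrt(M)).
    """
    geo = spec.eat_geometry.resolve(spec.grid_size)
    lo, hi = spec.eat_slice_range
    s2 = spec.pixel_spacing ** 2
    areas = np.zeros(spec.n_slices)
    for j in range(spec.n_eat_slices):
        areas[lo + j] = geo.sector_area_px(j, spec.n_eat_slices) * s2
    labels = (areas > 0).astype(int)
    z = spec.z_positions()
    sel = np.nonzero(labels)[0]
    a, zz = areas[sel], z[sel]
    eatv_mm3 = float(np.sum((a[:-1] + a[1:]) / 2.0 * np.diff(zz))) if len(sel) > 1 else 0.0
    return GroundTruth(
        eatv_ml=eatv_mm3 / 1000.0,
        eatd_hu=float(spec.eat_hu_mean),
        per_slice_areas=areas,
        slice_labels=labels,
    )


def _rasterize_ring(spec: PhantomSpec, geo: EATGeometry, j: int) -> np.ndarray:
    g = spec.grid_size
    cx, cy = geo.center
    yy, xx = np.mgrid[0:g, 0:g]
    px, py = xx + 0.5 - cx, yy + 0.5 - cy
    d = np.hypot(px, py)
    rh, rp = geo.radii(j, spec.n_eat_slices)
    ang = (np.arctan2(py, px) - geo.sector_start) % (2.0 * math.pi)
    return (d >= rh) & (d < rp) & (ang < geo.sector_fraction * 2.0 * math.pi)


def _background(spec: PhantomSpec, heart_r: float, geo: EATGeometry) -> np.ndarray:
    g = spec.grid_size
    hu = spec.background_hu_levels
    yy, xx = np.mgrid[0:g, 0:g]
    img = np.full((g, g), hu["air"], dtype=np.float32)
    cx, cy = g / 2.0, g / 2.0
    body = ((xx + 0.5 - cx) / (0.46 * g)) ** 2 + ((yy + 0.5 - cy) / (0.40 * g)) ** 2 <= 1
    img[body] = hu["body"]
    for sgn in (-1, 1):
        lung = (
            ((xx + 0.5 - (cx + sgn * 0.27 * g)) / (0.13 * g)) ** 2
            + ((yy + 0.5 - cy) / (0.22 * g)) ** 2
            <= 1
        )
        img[lung & body] = hu["lung"]
    hx, hy = geo.center
    heart = np.hypot(xx + 0.5 - hx, yy + 0.5 - hy) < heart_r
    img[heart] = hu["heart"]
    return img


def generate_phantom_series(spec: PhantomSpec) -> tuple[CTSeries, MaskSeries, GroundTruth]:
    """Rasterize a phantom: HU slices, aligned binary EAT masks, ground truth.

    Deterministic for a fixed ``spec.seed``; with ``noise_sd == 0`` and
    ``eat_hu_sd == 0`` every masked voxel carries exactly ``eat_hu_mean`` HU.
    """
    geo = spec.eat_geometry.resolve(spec.grid_size)
    gt = analytic_ground_truth(spec)
    rng = np.random.default_rng([int(spec.seed) % (2 ** 31), 23])
    z = spec.z_positions()
    lo, hi = spec.eat_slice_range
    s = spec.pixel_spacing

    slices, masks = [], []
    for i in range(spec.n_slices):
        in_block = lo <= i <= hi
        j = i - lo
        # heart disc follows the ring profile inside the block, shrinks outside
        if in_block:
            heart_r, _ = geo.radii(j, spec.n_eat_slices)
        else:
            dist = min(abs(i - lo), abs(i - hi))
            heart_r = geo.heart_radius * geo.taper * max(0.2, 1.0 - 0.25 * dist)
        img = _background(spec, heart_r, geo)

        mask = np.zeros((spec.grid_size, spec.grid_size), dtype=bool)
        if in_block:
            mask = _rasterize_ring(spec, geo, j)
            vals = np.full(mask.sum(), spec.eat_hu_mean, dtype=np.float32)
            if spec.eat_hu_sd > 0:
                vals = vals + rng.normal(0.0, spec.eat_hu_sd, size=vals.shape).astype(np.float32)
            img[mask] = vals

        if spec.distractor_blobs and in_block:
            for _ in range(spec.distractor_blobs):
                bx = rng.uniform(0.15, 0.85) * spec.grid_size
                by = rng.uniform(0.62, 0.85) * spec.grid_size
                br = rng.uniform(0.02, 0.04) * spec.grid_size
                yy, xx = np.mgrid[0 : spec.grid_size, 0 : spec.grid_size]
                blob = np.hypot(xx + 0.5 - bx, yy + 0.5 - by) < br
                img[blob & ~mask] = spec.eat_hu_mean

        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
        # the fat HU window must hold for every labeled voxel, noise included
        img[mask] = np.clip(img[mask], *HU_FAT_WINDOW)

        slices.append(
            CTSlice(pixels=img, sx=s, sy=s, z=float(z[i]), patient_id=spec.patient_id, index=i)
        )
        masks.append(BinaryMask(grid=mask.astype(np.uint8), sx=s, sy=s))

    return CTSeries(slices=slices, patient_id=spec.patient_id), MaskSeries(masks), gt


def generate_phantom_cohort(
    n_patients: int,
    seed: int = 0,
    grid_size: int = 512,
    n_slices_range: tuple[int, int] = (10, 16),
    noise_sd: float = 5.0,
    eat_hu_sd: float = 12.0,
    **spec_overrides,
) -> list[PhantomSpec]:
    """Specs for a cohort with per-patient size/geometry variation.

    Heart size, ring thickness, slice count and EAT block vary between
    patients so cohort EATv spans a wide range — the spread the agreement
    statistics (Pearson r, Bland–Altman) need to be meaningful.
    """
    rng = np.random.default_rng([int(seed) % (2 ** 31), 31])
    specs = []
    for p in range(n_patients):
        n_slices = int(rng.integers(n_slices_range[0], n_slices_range[1] + 1))
        n_eat = int(rng.integers(max(4, n_slices // 3), n_slices - 2))
        lo = int(rng.integers(1, n_slices - n_eat))
        geo = EATGeometry(
            heart_radius=float(rng.uniform(0.12, 0.19)) * grid_size,
            eat_thickness=float(rng.uniform(0.05, 0.11)) * grid_size,
            sector_fraction=float(rng.uniform(0.6, 0.95)),
            sector_start=float(rng.uniform(0, 2 * math.pi)),
        )
        specs.append(
            PhantomSpec(
                n_slices=n_slices,
                eat_slice_range=(lo, lo + n_eat - 1),
                grid_size=grid_size,
                pixel_spacing=float(rng.uniform(0.6, 0.8)),
                eat_geometry=geo,
                # quantized to 1/8 HU so the value is float32-exact and a
                # noiseless phantom's mean attenuation recovers it bit-for-bit
                eat_hu_mean=float(np.round(rng.uniform(-120, -60) * 8) / 8),
                eat_hu_sd=eat_hu_sd,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2 ** 31)),
                patient_id=f"phantom-{p:03d}",
                **spec_overrides,
            )
        )
    return specs


def write_phantom_cohort(
    specs: Sequence[PhantomSpec], out_dir: str | os.PathLike, mask_format: str = "nifti"
) -> Path:
    """Write each phantom as NIfTI volume + mask, with a JSON cohort manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for spec in specs:
        series, masks, gt = generate_phantom_series(spec)
        ct_path = out / f"{spec.patient_id}_ct.nii.gz"
        write_ct_series(series, ct_path)
        if mask_format == "png":
            mask_path = out / f"{spec.patient_id}_masks"
        else:
            mask_path = out / f"{spec.patient_id}_mask.nii.gz"
        write_mask_series(masks, mask_path, format=mask_format, z_positions=series.z_positions)
        manifest.append(
            {
                "patient_id": spec.patient_id,
                "ct": ct_path.name,
                "mask": mask_path.name,
                "pixel_spacing": spec.pixel_spacing,
                "z_positions": series.z_positions.tolist(),
                "slice_labels": gt.slice_labels.tolist(),
                "eatv_ml": gt.eatv_ml,
                "eatd_hu": gt.eatd_hu,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out / "manifest.json"
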