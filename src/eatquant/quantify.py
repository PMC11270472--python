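"""EAT volume (EATv) and mean attenuation (EATd) from slices and masks.

Volume integrates per-slice EAT areas by the trapezoidal rule over the true
inter-slice distances:

    A_i = n_i * s_x * s_y            (pixel count x pixel area, mm^2)
    v_i = (A_i + A_{i+1}) / 2 * dz_i (inter-slice volume, mm^3)
    V   = sum_i v_i / 1000           (mL)

Attenuation is the plain mean of HU values over all masked pixels across
slices, restricted to the conventional adipose window [-190, -30] HU; pixels
outside the window are excluded from both the sum and the pixel count M, so
EATd always lies inside the window when defined.  Volume, by contrast, uses
every mask pixel with no HU filtering — predicted masks need no
post-processing — though both filters are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .image_io import BinaryMask, CTSeries, MaskSeries

HU_RANGE_DEFAULT = (-190.0, -30.0)


class QuantifyError(ValueError):
    pass


@dataclass
class QuantConfig:
    hu_range: tuple = HU_RANGE_DEFAULT
    attenuation_hu_filter: bool = True  # Eq-8 window applied to EATd
    volume_hu_filter: bool = False  # volume counts every mask pixel
    nominal_thickness: float = 3.0  # mm, single-slice fallback
    max_gap_warn: float = 10.0  # mm, flag suspicious z jumps


@dataclass
class QuantResult:
    """Per-patient quantification output."""

    patient_id: str
    eatv_ml: float
    eatd_hu: float  # nan when undefined (no in-window pixels)
    n_slices_used: int
    n_pixels_used: int
    per_slice_areas_mm2: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_slice_pixels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    warnings: list = field(default_factory=list)

    @property
    def eatd_defined(self) -> bool:
        return np.isfinite(self.eatd_hu)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "eatv_ml": self.eatv_ml,
            "eatd_hu": None if not self.eatd_defined else self.eatd_hu,
            "n_slices_used": self.n_slices_used,
            "n_pixels_used": self.n_pixels_used,
            "warnings": list(self.warnings),
        }


def slice_area(mask: BinaryMask) -> float:
    """EAT cross-sectional area of one slice: foreground pixels x sx x sy, mm^2."""
    if not isinstance(mask, BinaryMask):
        raise QuantifyError("slice_area needs a BinaryMask (grid + spacing)")
    return float(mask.n_foreground) * mask.sx * mask.sy


def volume_from_areas(
    areas: Sequence[float],
    z_positions: Sequence[float],
    single_slice_thickness: float | None = None,
) -> float:
    """Trapezoidal volume of per-slice areas over slice z positions, in mL.

    A single slice has no gap to integrate over; it contributes
    ``area * single_slice_thickness`` (which must then be provided).
    """
    a = np.asarray(areas, dtype=float)
    z = np.asarray(z_positions, dtype=float)
    if a.size == 0:
        raise QuantifyError("need at least one area")
    if a.shape != z.shape:
        raise QuantifyError(f"{a.size} areas but {z.size} z positions")
    if np.any(a < 0):
        raise QuantifyError("areas must be nonnegative")
    if a.size == 1:
        if single_slice_thickness is None:
            raise QuantifyError("single slice: provide single_slice_thickness")
        return float(a[0]) * float(single_slice_thickness) / 1000.0
    dz = np.diff(z)
    if np.any(dz <= 0):
        raise QuantifyError("z positions must be strictly increasing")
    return float(np.sum((a[:-1] + a[1:]) / 2.0 * dz)) / 1000.0


@dataclass
class AttenuationResult:
    eatd_hu: float  # nan when undefined
    m: int  # total in-window mask pixels
    per_slice_pixels: np.ndarray

    @property
    def defined(self) -> bool:
        return np.isfinite(self.eatd_hu)


def attenuation_from_masks(
    series: CTSeries,
    masks: MaskSeries,
    hu_range: tuple[float, float] = HU_RANGE_DEFAULT,
) -> AttenuationResult:
    """Mean HU over masked pixels inside ``hu_range``.

    Out-of-window pixels are excluded from numerator *and* denominator.  With
    no qualifying pixel the attenuation is undefined (nan), never silently 0.
    """
    masks.validate_against(series)
    lo, hi = hu_range
    if not lo < hi:
        raise QuantifyError(f"hu_range low must be < high, got {hu_range}")
    total, m = 0.0, 0
    counts = np.zeros(len(series), dtype=int)
    for i, (s, msk) in enumerate(zip(series, masks)):
        sel = msk.grid.astype(bool)
        if not sel.any():
            continue
        vals = s.pixels[sel]
        vals = vals[(vals >= lo) & (vals <= hi)]
        counts[i] = vals.size
        total += float(vals.sum(dtype=np.float64))
        m += vals.size
    eatd = total / m if m > 0 else float("nan")
    return AttenuationResult(eatd_hu=eatd, m=m, per_slice_pixels=counts)


def quantify_patient(
    series: CTSeries,
    masks: MaskSeries,
    config: QuantConfig | None = None,
) -> QuantResult:
    """Combine area, volume and attenuation over the mask-bearing slices.

    Slices with empty masks are not part of the integration; consecutive
    selected slices are integrated over their true z gaps (a gap larger than
    ``max_gap_warn`` mm is flagged, not capped).
    """
    cfg = config or QuantConfig()
    masks.validate_against(series)
    warnings: list[str] = []

    sel = [i for i, m in enumerate(masks) if m.n_foreground > 0]
    areas = np.array([slice_area(masks[i]) for i in sel])
    if cfg.volume_hu_filter:
        lo, hi = cfg.hu_range
        areas = np.array(
            [
                float(
                    np.count_nonzero(
                        masks[i].grid.astype(bool)
                        & (series[i].pixels >= lo)
                        & (series[i].pixels <= hi)
                    )
                )
                * masks[i].sx
                * masks[i].sy
                for i in sel
            ]
        )
    z = series.z_positions[sel]

    if not sel:
        warnings.append("no mask-bearing slices: zero volume, undefined attenuation")
        return QuantResult(
            patient_id=series.patient_id, eatv_ml=0.0, eatd_hu=float("nan"),
            n_slices_used=0, n_pixels_used=0, warnings=warnings,
        )

    if len(sel) == 1:
        gaps = series.z_gaps
        t = float(np.median(gaps)) if gaps.size else cfg.nominal_thickness
        warnings.append(f"single mask-bearing slice: volume uses thickness {t:g} mm")
        eatv = volume_from_areas(areas, z, single_slice_thickness=t)
    else:
        big = np.diff(z)
        if np.any(big > cfg.max_gap_warn):
            warnings.append(
                f"z gap(s) above {cfg.max_gap_warn:g} mm between selected slices: "
                f"max {big.max():.1f} mm"
            )
        eatv = volume_from_areas(areas, z)

    att = attenuation_from_masks(series, masks, cfg.hu_range if cfg.attenuation_hu_filter
                                 else (-np.inf, np.inf))
    if not att.defined:
        warnings.append("no mask pixels inside the HU window: attenuation undefined")

    return QuantResult(
        patient_id=series.patient_id,
        eatv_ml=eatv,
        eatd_hu=att.eatd_hu,
        n_slices_used=len(sel),
        n_pixels_used=att.m,
        per_slice_areas_mm2=areas,
        per_slice_pixels=att.per_slice_pixels[sel],
        warnings=warnings,
    )
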