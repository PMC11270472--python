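"""Reading and writing CT series and mask stacks.

CT slices carry Hounsfield-unit (HU) pixel values together with the spatial
metadata the downstream quantification needs: in-plane pixel spacing ``(sx, sy)``
in mm and the slice position ``z`` in mm along the scan axis.  Series are always
kept sorted by ascending ``z`` so that inter-slice gaps are positive.

Supported formats: DICOM series directories (via :mod:`pydicom`), NIfTI-1
volumes (via :mod:`nibabel`), and per-slice PNG mask stacks (foreground stored
as 255).  Stored integer values are converted to HU through the format's linear
rescale (slope/intercept) on read.
"""

from __future__ import annotations

import json
import math
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np


class ImageIOError(RuntimeError):
    """Raised when a series or mask stack cannot be read or validated."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CTSlice:
    """A single axial CT slice in Hounsfield units.

    Attributes
    ----------
    pixels : 2D float array of HU values.
    sx, sy : pixel spacing in mm (x and y directions); must be positive.
    z : slice position along the scan axis, mm.
    patient_id : identifier of the originating series.
    index : position of the slice within its (z-sorted) series.
    """

    pixels: np.ndarray
    sx: float
    sy: float
    z: float
    patient_id: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ImageIOError(f"slice pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ImageIOError("slice pixels contain non-finite values")
        if self.sx <= 0 or self.sy <= 0:
            raise ImageIOError(f"pixel spacing must be positive, got ({self.sx}, {self.sy})")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CTSeries:
    """An ordered stack of axial slices with strictly increasing z."""

    slices: list[CTSlice]
    patient_id: str = ""

    def __post_init__(self) -> None:
        if not self.slices:
            raise ImageIOError("a CT series needs at least one slice")
        self.slices = sorted(self.slices, key=lambda s: s.z)
        z = self.z_positions
        if len(z) > 1 and np.any(np.diff(z) <= 0):
            raise ImageIOError("slice z positions must be strictly increasing (duplicate z?)")
        for i, s in enumerate(self.slices):
            s.index = i
            if not s.patient_id:
                s.patient_id = self.patient_id

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[CTSlice]:
        return iter(self.slices)

    def __getitem__(self, i: int) -> CTSlice:
        return self.slices[i]

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([s.z for s in self.slices], dtype=float)

    @property
    def z_gaps(self) -> np.ndarray:
        """Scalar gaps between consecutive slices along the sorted axis, mm."""
        return np.diff(self.z_positions)

    @property
    def spacing(self) -> tuple[float, float]:
        return (self.slices[0].sx, self.slices[0].sy)

    def stack(self) -> np.ndarray:
        """All slices as one (n_slices, H, W) HU array."""
        return np.stack([s.pixels for s in self.slices])


@dataclass
class BinaryMask:
    """A per-slice 0/1 mask sharing the grid and spacing of its CT slice."""

    grid: np.ndarray
    sx: float
    sy: float

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        vals = np.unique(g)
        if not np.all(np.isin(vals, (0, 1))):
            raise ImageIOError(f"mask values must be 0/1, found {vals[:5]}")
        self.grid = g.astype(np.uint8)
        if self.sx <= 0 or self.sy <= 0:
            raise ImageIOError("mask pixel spacing must be positive")

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())


@dataclass
class MaskSeries:
    """Masks aligned one-to-one with the slices of a CT series."""

    masks: list[BinaryMask]

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self) -> Iterator[BinaryMask]:
        return iter(self.masks)

    def __getitem__(self, i: int) -> BinaryMask:
        return self.masks[i]

    def stack(self) -> np.ndarray:
        return np.stack([m.grid for m in self.masks])

    def validate_against(self, series: CTSeries) -> None:
        if len(self.masks) != len(series):
            raise ImageIOError(
                f"mask count {len(self.masks)} != series slice count {len(series)}"
            )
        for m, s in zip(self.masks, series):
            if m.grid.shape != s.pixels.shape:
                raise ImageIOError(
                    f"mask grid {m.grid.shape} does not match slice grid {s.pixels.shape}"
                )


@dataclass
class SplitResult:
    """Train/validation/test index membership produced by :func:`split_dataset`."""

    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray
    seed: int = 0

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_ids), len(self.val_ids), len(self.test_ids))

    def to_csv(self, path: str | os.PathLike) -> None:
        import pandas as pd

        rows = (
            [(int(i), "train") for i in self.train_ids]
            + [(int(i), "val") for i in self.val_ids]
            + [(int(i), "test") for i in self.test_ids]
        )
        pd.DataFrame(rows, columns=["index", "split"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

def split_dataset(
    n_images: int,
    holdout_fraction: float = 0.15,
    seed: int = 0,
    groups: Sequence[int] | None = None,
) -> SplitResult:
    """Randomly split ``n_images`` into train / validation / test sets.

    The held-out pool is ``floor(n * holdout_fraction)`` rounded down to the
    nearest even integer and is divided into two equal halves (validation and
    test); the remainder trains.  With the study sizes this yields
    41,979 -> (35,683, 3,148, 3,148) and 23,771 -> (20,207, 1,782, 1,782).

    Parameters
    ----------
    groups : optional per-image group (e.g. patient) ids.  When given, whole
        groups are assigned to one side of the split so no group leaks across
        sets; the even-holdout size rule then applies to groups, not images.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError(f"holdout_fraction must be in (0, 1), got {holdout_fraction}")
    rng = np.random.default_rng(seed)

    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != n_images:
            raise ValueError("groups must have one entry per image")
        uniq = np.unique(groups)
        gsplit = split_dataset(len(uniq), holdout_fraction, seed)
        val_g = set(uniq[gsplit.val_ids].tolist())
        test_g = set(uniq[gsplit.test_ids].tolist())
        idx = np.arange(n_images)
        val = idx[[g in val_g for g in groups]]
        test = idx[[g in test_g for g in groups]]
        train = idx[[(g not in val_g) and (g not in test_g) for g in groups]]
        return SplitResult(train, val, test, seed)

    n_holdout = int(math.floor(n_images * holdout_fraction))
    n_holdout -= n_holdout % 2  # two equal halves
    if n_holdout < 2:
        raise ValueError(
            f"n_images={n_images} too small for a nonempty even holdout at "
            f"fraction {holdout_fraction}"
        )
    perm = rng.permutation(n_images)
    half = n_holdout // 2
    val = np.sort(perm[:half])
    test = np.sort(perm[half:n_holdout])
    train = np.sort(perm[n_holdout:])
    return SplitResult(train, val, test, seed)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _nifti_series_from_img(img, patient_id: str) -> CTSeries:
    import nibabel as nib

    zooms = img.header.get_zooms()[:3]
    if any((not np.isfinite(v)) or v <= 0 for v in zooms):
        raise ImageIOError(
            f"NIfTI header of '{patient_id}' has invalid pixel spacing (pixdim={zooms})"
        )
    sx, sy, sz = (float(v) for v in zooms)
    # get_fdata applies scl_slope/scl_inter, i.e. the linear rescale to HU
    data = np.asanyarray(img.get_fdata(dtype=np.float32))
    if data.ndim != 3:
        raise ImageIOError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    affine = img.affine
    n = data.shape[2]
    # z position of slice k from the affine's third column/translation
    z0, dz = float(affine[2, 3]), float(affine[2, 2])
    if dz == 0:
        dz = sz
    zs = z0 + dz * np.arange(n)
    slices = [
        CTSlice(pixels=data[:, :, k].T, sx=sx, sy=sy, z=float(zs[k]), patient_id=patient_id)
        for k in range(n)
    ]
    return CTSeries(slices=slices, patient_id=patient_id)


def write_ct_series(series: CTSeries, path: str | os.PathLike) -> None:
    """Write a series as a single 3D NIfTI volume (HU values, spacing in header)."""
    import nibabel as nib

    sx, sy = series.spacing
    z = series.z_positions
    dz = float(np.median(np.diff(z))) if len(z) > 1 else 1.0
    vol = np.stack([s.pixels.T for s in series], axis=2).astype(np.float32)
    affine = np.diag([sx, sy, dz, 1.0])
    affine[2, 3] = z[0]
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((sx, sy, dz))
    nib.save(img, os.fspath(path))


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def _read_dicom_dir(path: Path) -> CTSeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    if not files:
        raise ImageIOError(f"no DICOM files found in {path}")
    datasets = [pydicom.dcmread(os.fspath(f)) for f in files]

    pids = {str(getattr(ds, "PatientID", "")) for ds in datasets}
    if len(pids) > 1:
        raise ImageIOError(f"directory {path} mixes patients: {sorted(pids)}")
    patient_id = pids.pop()

    slices = []
    for ds, f in zip(datasets, files):
        if "PixelSpacing" not in ds:
            raise ImageIOError(f"{f.name}: missing PixelSpacing")
        if "ImagePositionPatient" not in ds and "SliceLocation" not in ds:
            raise ImageIOError(f"{f.name}: missing ImagePositionPatient/SliceLocation")
        z = float(ds.ImagePositionPatient[2]) if "ImagePositionPatient" in ds else float(
            ds.SliceLocation
        )
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float32) * slope + intercept
        sy_, sx_ = (float(v) for v in ds.PixelSpacing)  # DICOM order: row, col
        slices.append(CTSlice(pixels=hu, sx=sx_, sy=sy_, z=z, patient_id=patient_id))
    return CTSeries(slices=slices, patient_id=patient_id)


def read_ct_series(path: str | os.PathLike, patient_id: str | None = None) -> CTSeries:
    """Read a CT series from a DICOM directory or a NIfTI file.

    Slices are returned sorted by ascending z, with stored values converted to
    HU via the format's linear rescale.  Missing spacing or position metadata
    raises :class:`ImageIOError` naming the missing field.
    """
    import nibabel as nib

    p = Path(path)
    if p.is_dir():
        series = _read_dicom_dir(p)
    elif p.suffix in (".nii",) or p.name.endswith(".nii.gz"):
        pid = patient_id or re.sub(r"\.nii(\.gz)?$", "", p.name)
        series = _nifti_series_from_img(nib.load(os.fspath(p)), pid)
    else:
        raise ImageIOError(f"unrecognized CT input: {path}")
    if patient_id:
        series.patient_id = patient_id
        for s in series:
            s.patient_id = patient_id
    return series


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def write_mask_series(
    masks: MaskSeries,
    path: str | os.PathLike,
    format: str = "nifti",
    z_positions: Sequence[float] | None = None,
) -> None:
    """Write a mask stack as NIfTI (0/1 volume) or a directory of PNGs (0/255)."""
    import nibabel as nib

    p = Path(path)
    if format == "nifti":
        sx, sy = masks[0].sx, masks[0].sy
        z = np.asarray(z_positions, dtype=float) if z_positions is not None else np.arange(
            len(masks), dtype=float
        )
        dz = float(np.median(np.diff(z))) if len(z) > 1 else 1.0
        vol = np.stack([m.grid.T for m in masks], axis=2).astype(np.uint8)
        affine = np.diag([sx, sy, dz, 1.0])
        affine[2, 3] = z[0]
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((sx, sy, dz))
        nib.save(img, os.fspath(p))
    elif format == "png":
        from PIL import Image

        p.mkdir(parents=True, exist_ok=True)
        meta = {"sx": masks[0].sx, "sy": masks[0].sy, "n": len(masks)}
        (p / "masks.json").write_text(json.dumps(meta))
        for i, m in enumerate(masks):
            Image.fromarray((m.grid * 255).astype(np.uint8)).save(p / f"mask_{i:04d}.png")
    else:
        raise ValueError(f"unknown mask format {format!r} (use 'nifti' or 'png')")


def read_mask_series(path: str | os.PathLike, series: CTSeries | None = None) -> MaskSeries:
    """Read a mask stack written by :func:`write_mask_series`.

    PNG foreground (255) is mapped back to 1.  If ``series`` is given, the
    stack is validated against it (same slice count and grid).
    """
    import nibabel as nib

    p = Path(path)
    if p.is_dir():
        from PIL import Image

        meta = json.loads((p / "masks.json").read_text())
        masks = []
        for i in range(meta["n"]):
            arr = np.asarray(Image.open(p / f"mask_{i:04d}.png"))
            masks.append(BinaryMask(grid=(arr > 127).astype(np.uint8), sx=meta["sx"], sy=meta["sy"]))
        ms = MaskSeries(masks)
    else:
        img = nib.load(os.fspath(p))
        zooms = img.header.get_zooms()[:3]
        sx, sy = float(zooms[0]), float(zooms[1])
        vol = np.asanyarray(img.dataobj)
        ms = MaskSeries(
            [
                BinaryMask(grid=(vol[:, :, k].T > 0).astype(np.uint8), sx=sx, sy=sy)
                for k in range(vol.shape[2])
            ]
        )
    if series is not None:
        ms.validate_against(series)
    return ms
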