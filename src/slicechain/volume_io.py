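"""Volume and mask I/O with physical spacing metadata.

Coordinate convention used by every module in this package:

* voxel arrays are indexed ``(slice, row, column)``, 0-based;
* the slice axis runs inferior -> superior with increasing index;
* ``spacing`` is ``(dz, dy, dx)`` in millimetres, all strictly positive.

NIfTI is the canonical interchange format; NRRD and (read-only) DICOM
series are also supported.  Masks are stored as 8-bit 0/1 NIfTI/NRRD
payloads; any nonzero voxel read from disk is treated as foreground.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

from .exceptions import ValidationError

__all__ = [
    "CTVolume",
    "BinaryMask",
    "Case",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

#: tolerance on slice-gap uniformity, as a fraction of the median gap
SLICE_GAP_TOLERANCE = 0.01


@dataclass
class CTVolume:
    """A 3D scalar image with physical spacing.

    Attributes
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Intensities in HU-like units (or [0, 1] after normalization).
    spacing : tuple (dz, dy, dx)
        Voxel spacing in mm, all strictly positive.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValidationError(
                f"volume must be a non-empty 3D grid, got shape {self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class BinaryMask:
    """A boolean grid aligned to a :class:`CTVolume` (1 = inside the contour)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValidationError(
                f"mask must be a non-empty 3D grid, got shape {self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class Case:
    """One subject: a volume plus (optionally) its ground-truth mask."""

    volume: CTVolume
    mask: Optional[BinaryMask] = None
    case_id: str = field(default="case")

    def __post_init__(self) -> None:
        if self.mask is not None and self.mask.shape != self.volume.shape:
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match volume shape {self.volume.shape}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _is_nrrd(path: Path) -> bool:
    return path.suffix.lower() == ".nrrd"


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz) in voxel order (i, j, k)
    # on-disk order is (col, row, slice); transpose to (slice, row, col)
    voxels = np.ascontiguousarray(data.transpose(2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return voxels, spacing


def _write_nifti(voxels: np.ndarray, spacing: Sequence[float], path: Path) -> None:
    dz, dy, dx = spacing
    affine = np.diag([dx, dy, dz, 1.0])
    data = np.ascontiguousarray(np.asarray(voxels).transpose(2, 1, 0))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))


def _read_nrrd(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    voxels = sitk.GetArrayFromImage(img)  # already (z, y, x)
    if voxels.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D image, got shape {voxels.shape}")
    sx, sy, sz = img.GetSpacing()
    return np.ascontiguousarray(voxels), (float(sz), float(sy), float(sx))


def _write_nrrd(voxels: np.ndarray, spacing: Sequence[float], path: Path) -> None:
    import SimpleITK as sitk

    dz, dy, dx = spacing
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels))
    img.SetSpacing((float(dx), float(dy), float(dz)))
    sitk.WriteImage(img, str(path))


def _read_dicom_series(directory: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue  # skip non-DICOM files in the directory
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValidationError(f"{directory}: no readable DICOM slices found")

    series_uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(series_uids) > 1:
        raise ValidationError(
            f"{directory}: mixed DICOM series in one directory: {sorted(series_uids)}"
        )

    def z_position(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "SliceLocation", 0.0))

    datasets.sort(key=z_position)
    zs = np.array([z_position(ds) for ds in datasets], dtype=float)
    if len(zs) < 2:
        raise ValidationError(f"{directory}: a DICOM series needs at least two slices")
    gaps = np.diff(zs)
    median_gap = float(np.median(gaps))
    if median_gap <= 0:
        raise ValidationError(f"{directory}: non-increasing slice positions {zs.tolist()}")
    bad = [float(g) for g in gaps if abs(g - median_gap) > SLICE_GAP_TOLERANCE * median_gap]
    if bad:
        raise ValidationError(
            f"{directory}: non-uniform slice spacing; median gap {median_gap} mm, "
            f"offending gaps {bad} mm"
        )

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)

    ps = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])  # (row, col)
    spacing = (median_gap, float(ps[0]), float(ps[1]))
    return voxels, spacing


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT-like volume from NIfTI, NRRD, or a directory of DICOM slices.

    DICOM slices are sorted by slice position ascending (inferior -> superior)
    and rescaled to HU where rescale metadata exists.  Non-uniform slice
    spacing beyond 1% of the median gap raises :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        voxels, spacing = _read_dicom_series(path)
    elif _is_nifti(path):
        voxels, spacing = _read_nifti(path)
    elif _is_nrrd(path):
        voxels, spacing = _read_nrrd(path)
    else:
        raise ValidationError(f"unsupported volume format: {path.name}")
    return CTVolume(voxels=voxels, spacing=spacing)


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or NRRD, chosen by extension."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if _is_nifti(path):
        _write_nifti(vol.voxels, vol.spacing, path)
    elif _is_nrrd(path):
        _write_nrrd(vol.voxels, vol.spacing, path)
    else:
        raise ValidationError(f"unsupported volume format: {path.name}")


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask with an 8-bit 0/1 payload (NIfTI or NRRD by extension)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    payload = mask.voxels.astype(np.uint8)
    if _is_nifti(path):
        _write_nifti(payload, mask.spacing, path)
    elif _is_nrrd(path):
        _write_nrrd(payload, mask.spacing, path)
    else:
        raise ValidationError(f"unsupported mask format: {path.name}")


def read_mask(path: str | os.PathLike, reference: CTVolume) -> BinaryMask:
    """Read a mask and validate it against a reference volume.

    Any nonzero voxel is treated as foreground.  A shape mismatch with the
    reference raises :class:`ValidationError` naming both shapes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if _is_nifti(path):
        voxels, _ = _read_nifti(path)
    elif _is_nrrd(path):
        voxels, _ = _read_nrrd(path)
    else:
        raise ValidationError(f"unsupported mask format: {path.name}")
    if voxels.shape != reference.shape:
        raise ValidationError(
            f"mask shape {voxels.shape} does not match reference volume shape {reference.shape}"
        )
    return BinaryMask(voxels=voxels != 0, spacing=reference.spacing)
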