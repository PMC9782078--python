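"""CT volume container and medical-image I/O.

A :class:`CTVolume` is a 3-D grid of Hounsfield units (HU) indexed
``(z, y, x)`` — axial slice first — with physical voxel spacing in mm per
axis.  Air is close to −1000 HU, water 0 HU, soft tissue a few tens of HU,
bone several hundred.  Volumes round-trip through NIfTI (via nibabel) and
can be loaded from DICOM series (via pydicom) with the rescale slope and
intercept applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class CTVolume:
    """3-D Hounsfield-unit grid with physical spacing.

    Parameters
    ----------
    hu : ndarray, shape (nz, ny, nx)
        Hounsfield values, axial slice first.
    spacing : tuple of float
        Voxel edge length in mm per axis, ordered ``(dz, dy, dx)``.
    """

    hu: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.hu.shape}")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU grid contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    def copy(self) -> "CTVolume":
        return CTVolume(self.hu.copy(), self.spacing)


def save_nifti(volume: CTVolume, path: str | Path, dtype=np.int16) -> None:
    """Write a volume as NIfTI with spacing in the header.

    HU values are stored as signed 16-bit by default (clipped to the dtype
    range); pass ``dtype=np.float32`` to keep fractional values.
    """
    import nibabel as nib

    data = volume.hu
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.round(data), info.min, info.max)
    # nibabel uses (x, y, z); our array is (z, y, x)
    arr = np.asarray(data, dtype=dtype).transpose(2, 1, 0)
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> CTVolume:
    """Read a NIfTI volume into a CTVolume (HU, (z,y,x) order)."""
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.get_fdata(), dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D NIfTI image, got shape {arr.shape}")
    zooms = img.header.get_zooms()[:3]
    return CTVolume(arr.transpose(2, 1, 0), (float(zooms[2]), float(zooms[1]), float(zooms[0])))


def load_dicom_series(directory: str | Path) -> CTVolume:
    """Load a single-series DICOM directory as a HU volume.

    Slices are ordered by ImagePositionPatient along the slice normal (or
    InstanceNumber as fallback); RescaleSlope/RescaleIntercept are applied so
    values are true Hounsfield units.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"{directory}: no readable DICOM images found")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    hu = np.stack(slices, axis=0)

    first = datasets[0]
    px = getattr(first, "PixelSpacing", [1.0, 1.0])
    if len(datasets) > 1:
        z0, z1 = sort_key(datasets[0]), sort_key(datasets[1])
        dz = abs(z1 - z0) or float(getattr(first, "SliceThickness", 1.0))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    return CTVolume(hu, (dz, float(px[0]), float(px[1])))
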