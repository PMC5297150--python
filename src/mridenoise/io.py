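"""Volume I/O: NIfTI-1 read/write and DICOM-series read.

NIfTI-1 (.nii / .nii.gz) is the canonical on-disk format; a DICOM series
directory can be read as input. Intensities are taken as stored (after the
format's own scale/intercept, which nibabel and pydicom apply); no
reorientation to anatomical axes is attempted — the stored array order
defines (row, column, slice) and denoising is orientation-agnostic.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .volume import ImageStack

__all__ = ["read_volume", "write_volume"]


def _read_nifti(path: Path) -> ImageStack:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        warnings.warn(f"{path}: missing or invalid voxel spacing; assuming 1 mm isotropic")
        zooms = (1.0, 1.0, 1.0)
    if np.any(data < 0):
        raise ValueError(
            f"{path}: volume contains negative intensities; magnitude MR data "
            "must be nonnegative (clip or offset the input before denoising)"
        )
    return ImageStack(data, tuple(float(z) for z in zooms), {"source": str(path)})


def _read_dicom_dir(path: Path) -> ImageStack:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"{path}: no readable DICOM slices found")

    def sort_key(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return int(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    arrs = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrs.append(arr * slope + intercept)
    data = np.stack(arrs, axis=-1)

    first = slices[0]
    if hasattr(first, "PixelSpacing"):
        row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    else:
        warnings.warn(f"{path}: PixelSpacing missing; assuming 1 mm in-plane")
        row_mm = col_mm = 1.0
    slice_mm = float(
        getattr(first, "SpacingBetweenSlices", getattr(first, "SliceThickness", 0.0)) or 0.0
    )
    if slice_mm <= 0:
        warnings.warn(f"{path}: slice spacing missing; assuming 1 mm")
        slice_mm = 1.0
    if np.any(data < 0):
        raise ValueError(f"{path}: negative intensities in DICOM series")
    return ImageStack(data, (row_mm, col_mm, slice_mm), {"source": str(path)})


def read_volume(path) -> ImageStack:
    """Read a NIfTI file or a DICOM series directory into an ImageStack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input volume not found: {path}")
    if path.is_dir():
        return _read_dicom_dir(path)
    return _read_nifti(path)


def write_volume(stack: ImageStack, path) -> None:
    """Write an ImageStack as NIfTI-1 (float32, spacing in the header)."""
    path = Path(path)
    affine = np.diag(list(stack.spacing) + [1.0])
    img = nib.Nifti1Image(stack.values.astype(np.float32), affine)
    img.header.set_zooms(stack.spacing)
    nib.save(img, str(path))
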