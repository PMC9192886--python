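"""NIfTI volume I/O and world-coordinate resampling onto the SPECT grid.

Arrays are stored ``(slice, row, col)``; the NIfTI affine is used for voxel
spacing only, with orientation assumed identity (simulator-native data).
Resampling maps voxel centres through world coordinates — the CT and SPECT
grids cover the same physical subject at different spacings, so a naive
array resize would misplace structures.
"""

from __future__ import annotations

import logging
import os
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage

from .exceptions import ContractError, FormatError
from .volume import GridSpec, Volume

log = logging.getLogger(__name__)


def write_volume(vol: Volume, path) -> None:
    """Write a volume as NIfTI-1 (.nii/.nii.gz); spacing goes in the header."""
    data = np.asarray(vol.data)
    if vol.modality == "mask":
        data = data.astype(np.uint8)
    elif data.dtype == np.int64:  # NIfTI-1 has no portable 64-bit int
        data = (data.astype(np.int32) if np.abs(data).max(initial=0) < 2 ** 31
                else data.astype(np.float64))
    affine = np.diag([*vol.voxel_size_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, os.fspath(path))


def read_volume(path, modality: str = "activity") -> Volume:
    """Read a NIfTI volume; spacing comes from the header zooms.

    Negative values in count volumes are clamped to zero with a logged
    warning (reconstruction can ring below zero; counts cannot).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # nibabel raises various types for bad headers
        raise FormatError(f"could not parse {path} as NIfTI: {exc}") from exc
    if data.ndim != 3:
        data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if modality == "spect_counts" and np.any(data < 0):
        n = int((data < 0).sum())
        log.warning("%s: clamping %d negative count voxels to zero", path, n)
        data = np.clip(data, 0, None)
    return Volume(data, tuple(float(z) for z in zooms), modality)


def read_dicom_series(directory, modality: str = "ct") -> Volume:
    """Read-only DICOM series ingestion (slices sorted by position) behind the
    same Volume contract.  Requires pydicom."""
    import pydicom

    files = sorted(os.path.join(directory, f) for f in os.listdir(directory)
                   if not f.startswith("."))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(f))
        except Exception as exc:
            raise FormatError(f"could not parse {f} as DICOM: {exc}") from exc
    slices.sort(key=lambda d: float(getattr(d, "ImagePositionPatient", [0, 0, 0])[2]))
    data = np.stack([s.pixel_array.astype(np.float64) for s in slices])
    first = slices[0]
    py, px = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        dz = abs(float(slices[1].ImagePositionPatient[2])
                 - float(first.ImagePositionPatient[2]))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    return Volume(data * slope + intercept, (dz, py, px), modality)


def resample_to_grid(vol: Volume, target: GridSpec, method: str = "trilinear",
                     source_origin_mm=(0.0, 0.0, 0.0),
                     fill_value: Optional[float] = None) -> Volume:
    """Resample onto ``target`` through world coordinates.

    ``method`` is ``trilinear`` or ``nearest``; masks must use nearest.
    Voxel values live at voxel centres; target positions outside the source
    field of view take ``fill_value`` (default 0, or the source minimum for
    CT so out-of-field stays air).
    """
    if method not in ("trilinear", "nearest"):
        raise ContractError(f"method must be 'trilinear' or 'nearest', got {method!r}")
    if vol.modality == "mask" and method != "nearest":
        raise ContractError("masks must be resampled with method='nearest'")
    if fill_value is None:
        fill_value = float(np.min(vol.data)) if vol.modality == "ct" else 0.0

    src_sp = np.asarray(vol.voxel_size_mm)
    tgt_sp = np.asarray(target.voxel_size_mm)
    src_o = np.asarray(source_origin_mm, dtype=float)
    tgt_o = np.asarray(target.origin_mm, dtype=float)

    # world position of target voxel centres -> fractional source index
    axes = [(tgt_o[a] + np.arange(target.shape[a]) * tgt_sp[a] - src_o[a]) / src_sp[a]
            for a in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    order = 1 if method == "trilinear" else 0
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=np.float64), np.stack([zz, yy, xx]),
        order=order, mode="constant", cval=fill_value)
    if vol.modality == "mask":
        out = out.astype(np.uint8)
    return Volume(out, target.voxel_size_mm, vol.modality)


def center_to_common_fov(vol: Volume, target: GridSpec) -> np.ndarray:
    """Source origin that centres the source field of view on the target's.

    Helper for the usual CT-to-SPECT case where the two acquisitions share an
    isocentre but record no absolute frame.
    """
    src_extent = np.asarray(vol.voxel_size_mm) * (np.asarray(vol.shape) - 1)
    tgt_extent = np.asarray(target.voxel_size_mm) * (np.asarray(target.shape) - 1)
    return np.asarray(target.origin_mm) + (tgt_extent - src_extent) / 2.0
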