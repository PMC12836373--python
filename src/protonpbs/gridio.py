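"""Read/write VoxelGrids as NRRD or MetaImage via SimpleITK.

The grid kind, value unit and the LETd no-data sentinel are carried in the
image metadata dictionary so a round trip preserves semantics.  Masks are
stored as 8-bit label maps.  An optional best-effort DICOM RT-Dose import is
provided behind :func:`read_dicom_rtdose`.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk

from .phantom import VoxelGrid

__all__ = ["write_grid", "read_grid", "read_dicom_rtdose"]

_META_PREFIX = "protonpbs_"


def write_grid(path, grid: VoxelGrid) -> None:
    """Write a grid as .nrrd or .mha (chosen by extension).

    The voxel-center world convention is preserved by shifting the ITK
    origin (which addresses voxel centers) by half a voxel.
    """
    arr = grid.values
    if grid.kind == "mask":
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o + 0.5 * s) for o, s in zip(grid.origin, grid.spacing)))
    img.SetMetaData(_META_PREFIX + "kind", grid.kind)
    for k, v in grid.meta.items():
        img.SetMetaData(_META_PREFIX + str(k), str(v))
    sitk.WriteImage(img, str(path))


def read_grid(path, kind: str | None = None) -> VoxelGrid:
    """Read a .nrrd/.mha grid; ``kind`` overrides the stored metadata."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float) - 0.5 * spacing
    meta = {}
    stored_kind = None
    for key in img.GetMetaDataKeys():
        if key.startswith(_META_PREFIX):
            short = key[len(_META_PREFIX):]
            if short == "kind":
                stored_kind = img.GetMetaData(key)
            else:
                meta[short] = img.GetMetaData(key)
    k = kind or stored_kind or "dose"
    return VoxelGrid(origin, spacing, arr, k, meta)


def read_dicom_rtdose(path) -> VoxelGrid:
    """Best-effort DICOM RT-Dose import (requires pydicom).

    Applies DoseGridScaling and maps the DICOM patient coordinates onto the
    grid's world frame.  Not bit-exact against any TPS export.
    """
    import pydicom  # optional dependency

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(float) * scaling  # frames, rows, cols = z, y, x
    values = arr.transpose(2, 1, 0)
    dx, dy = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if offsets.size > 1 else 1.0
    ipp = np.asarray([float(v) for v in ds.ImagePositionPatient])
    spacing = np.array([dx, dy, abs(dz)])
    origin = ipp - 0.5 * spacing
    return VoxelGrid(origin, spacing, values, "dose", {"unit": "Gy"})
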