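"""Readers and writers for density volumes, masks and label volumes.

Supported on-disk formats are MetaImage (``.mha``, ``.mhd``) and NIfTI-1
(``.nii``, ``.nii.gz``), both via SimpleITK.  Densities are always held in
memory as floating point mg HA/cm**3; integer payloads are converted on
read through a linear calibration ``density = stored * slope + intercept``
supplied either as arguments, as MetaImage header tags ``DensitySlope`` /
``DensityIntercept``, or as a JSON sidecar ``<file>.calib.json``.
Proprietary scanner formats (AIM/ISQ, DICOM series) are not parsed;
convert to MetaImage or NIfTI first.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import BinaryMask, DensityVolume, RemodellingLabelVolume, ScanMeta

__all__ = ["read_volume", "write_volume", "read_mask", "read_labels",
           "to_sitk", "from_sitk_density"]

_EXTENSIONS = {
    "metaimage": (".mha", ".mhd"),
    "nifti": (".nii", ".nii.gz"),
}


def _format_for(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _EXTENSIONS:
            raise ValueError(
                f"unsupported format {fmt!r}; supported: {sorted(_EXTENSIONS)}"
            )
        return fmt
    name = path.name.lower()
    for f, exts in _EXTENSIONS.items():
        if any(name.endswith(e) for e in exts):
            return f
    raise ValueError(
        f"cannot infer format from {path.name!r}; supported extensions: "
        f"{[e for exts in _EXTENSIONS.values() for e in exts]}"
    )


def to_sitk(volume) -> sitk.Image:
    """Convert a DensityVolume / BinaryMask / RemodellingLabelVolume to a
    SimpleITK image (identity direction, isotropic spacing)."""
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = sitk.GetImageFromArray(data)
    v = float(volume.voxel_size)
    img.SetSpacing((v, v, v))
    img.SetOrigin(tuple(volume.origin))
    return img


def _grid_from_sitk(img: sitk.Image) -> tuple[float, tuple[float, float, float]]:
    spacing = img.GetSpacing()
    if max(spacing) - min(spacing) > 1e-9 * max(spacing):
        raise ValueError(
            f"anisotropic voxels are not supported: spacing (x, y, z) = {spacing}"
        )
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            "volumes must be axis-aligned (identity direction cosines); "
            f"got {direction.tolist()}"
        )
    return float(spacing[0]), tuple(img.GetOrigin())


def from_sitk_density(img: sitk.Image, meta: ScanMeta | None = None) -> DensityVolume:
    voxel, origin = _grid_from_sitk(img)
    data = sitk.GetArrayFromImage(img).astype(np.float64)
    return DensityVolume(data, voxel, origin, meta or ScanMeta())


def _resolve_calibration(path: Path, img: sitk.Image,
                         slope: float | None, intercept: float | None):
    if slope is not None or intercept is not None:
        return float(slope if slope is not None else 1.0), float(intercept or 0.0)
    keys = set(img.GetMetaDataKeys())
    if "DensitySlope" in keys:
        return (float(img.GetMetaData("DensitySlope")),
                float(img.GetMetaData("DensityIntercept"))
                if "DensityIntercept" in keys else 0.0)
    sidecar = Path(str(path) + ".calib.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            d = json.load(fh)
        return float(d["slope"]), float(d.get("intercept", 0.0))
    return None


def read_volume(
    path: str | os.PathLike,
    format: str = "auto",
    slope: float | None = None,
    intercept: float | None = None,
    meta: ScanMeta | None = None,
) -> DensityVolume:
    """Read a calibrated density volume.

    Integer payloads require a calibration (slope, intercept); float
    payloads are assumed to already be in mg HA/cm**3.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _format_for(path, format)
    img = sitk.ReadImage(str(path))
    voxel, origin = _grid_from_sitk(img)
    arr = sitk.GetArrayFromImage(img)
    if np.issubdtype(arr.dtype, np.integer):
        calib = _resolve_calibration(path, img, slope, intercept)
        if calib is None:
            raise ValueError(
                f"{path.name} stores integer values; supply a density "
                "calibration via slope/intercept arguments, DensitySlope/"
                "DensityIntercept header tags, or a <file>.calib.json sidecar"
            )
        s, b = calib
        data = arr.astype(np.float64) * s + b
    else:
        data = arr.astype(np.float64)
        if slope is not None or intercept is not None:
            data = data * (slope if slope is not None else 1.0) + (intercept or 0.0)
    return DensityVolume(data, voxel, origin, meta or ScanMeta())


def read_mask(path: str | os.PathLike, format: str = "auto") -> BinaryMask:
    """Read a binary mask (any non-zero voxel is true)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _format_for(path, format)
    img = sitk.ReadImage(str(path))
    voxel, origin = _grid_from_sitk(img)
    return BinaryMask(sitk.GetArrayFromImage(img) != 0, voxel, origin)


def read_labels(path: str | os.PathLike, format: str = "auto") -> RemodellingLabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _format_for(path, format)
    img = sitk.ReadImage(str(path))
    voxel, origin = _grid_from_sitk(img)
    return RemodellingLabelVolume(sitk.GetArrayFromImage(img), voxel, origin)


def write_volume(volume, path: str | os.PathLike, format: str = "auto") -> None:
    """Write a volume, mask or label volume.

    Masks and labels are stored as 8-bit integers (lossless); densities as
    32-bit floats, so the round trip is exact to float32 quantisation.
    """
    path = Path(path)
    fmt = _format_for(path, format)
    exts = _EXTENSIONS[fmt]
    if not any(path.name.lower().endswith(e) for e in exts):
        raise ValueError(f"path {path.name!r} does not match format {fmt!r} ({exts})")
    img = to_sitk(volume)
    if isinstance(volume, DensityVolume):
        img = sitk.Cast(img, sitk.sitkFloat32)
    else:
        img = sitk.Cast(img, sitk.sitkUInt8)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path), useCompression=path.name.endswith(".gz"))
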