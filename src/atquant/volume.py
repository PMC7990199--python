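"""Volumetric containers and standard-format I/O.

All in-memory volumes use (z, y, x) axis order with spacing and origin stored in
the same order, in millimetres.  CT attenuation is kept in Hounsfield units and
clamped on ingest to the 12-bit CT range [-1024, 3071].  NIfTI-1 (.nii/.nii.gz)
and MetaImage (.mha/.mhd) are read and written through SimpleITK, whose pixel
arrays already come back in (z, y, x) order; spacing/origin headers are (x, y, z)
and are reversed on the way in and out.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import DimensionalityError, GeometryError

HU_MIN = -1024.0
HU_MAX = 3071.0

_FORMAT_EXT = {
    "nifti": ".nii.gz",
    "metaimage": ".mha",
}


def _as_tuple3(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected a 3-vector, got length {len(t)}")
    return t


@dataclass(frozen=True)
class Volume:
    """Base 3D scalar field with geometry metadata (axis order z, y, x)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = field(default="zyx", init=False)

    def __post_init__(self):
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise DimensionalityError(f"expected a 3D array, got {arr.ndim}D")
        object.__setattr__(self, "voxels", arr)
        object.__setattr__(self, "spacing", _as_tuple3(self.spacing))
        object.__setattr__(self, "origin", _as_tuple3(self.origin))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.voxels.flags.writeable = False

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def same_geometry(self, other: "Volume", atol: float = 1e-3) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_geometry(self, other: "Volume", what: str = "volumes"):
        if not self.same_geometry(other):
            raise GeometryError(
                f"{what} disagree: shapes {self.shape} vs {other.shape}, "
                f"spacings {self.spacing} vs {other.spacing}"
            )


@dataclass(frozen=True)
class CTVolume(Volume):
    """A CT scan in Hounsfield units, clamped to [-1024, 3071] on construction."""

    def __post_init__(self):
        arr = np.asarray(self.voxels, dtype=np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError("CT volume contains non-finite values")
        arr = np.clip(arr, HU_MIN, HU_MAX)
        object.__setattr__(self, "voxels", arr)
        super().__post_init__()

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        """New CTVolume with the same geometry and different data."""
        return CTVolume(voxels, self.spacing, self.origin)


@dataclass(frozen=True)
class BinaryMask(Volume):
    """A {0,1} mask aligned to a parent volume."""

    def __post_init__(self):
        arr = np.asarray(self.voxels)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq[:5]}")
        object.__setattr__(self, "voxels", arr.astype(np.uint8))
        super().__post_init__()

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)

    def with_voxels(self, voxels: np.ndarray) -> "BinaryMask":
        return BinaryMask(voxels, self.spacing, self.origin)


@dataclass(frozen=True)
class ProbabilityMap(Volume):
    """Per-voxel probabilities in [0, 1] aligned to a parent volume."""

    def __post_init__(self):
        arr = np.asarray(self.voxels, dtype=np.float32)
        if arr.size and (arr.min() < -1e-6 or arr.max() > 1 + 1e-6):
            raise ValueError("probability map values must lie in [0, 1]")
        object.__setattr__(self, "voxels", np.clip(arr, 0.0, 1.0))
        super().__post_init__()


def _format_for_path(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMAT_EXT:
            raise ValueError(f"unknown format {fmt!r}; use 'nifti' or 'metaimage'")
        return fmt
    p = str(path).lower()
    if p.endswith((".nii", ".nii.gz")):
        return "nifti"
    if p.endswith((".mha", ".mhd")):
        return "metaimage"
    raise ValueError(f"cannot infer image format from path {path!r}")


def read_volume(path, format: str | None = None, kind: str = "ct"):
    """Read a 3D image as a CTVolume / BinaryMask / ProbabilityMap.

    Parameters
    ----------
    path : str or Path
    format : optional {'nifti', 'metaimage'}; inferred from the extension if None.
    kind : {'ct', 'mask', 'probability'} selecting the returned container.
    """
    _format_for_path(path, format)  # validates
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as e:  # pragma: no cover - SimpleITK wraps I/O errors
        raise IOError(f"could not read image {path}: {e}") from e
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D scalar image, got {img.GetDimension()}D"
        )
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise DimensionalityError(f"{path}: expected a scalar image")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if kind == "ct":
        return CTVolume(arr, spacing, origin)
    if kind == "mask":
        return BinaryMask(arr != 0, spacing, origin)
    if kind == "probability":
        return ProbabilityMap(arr, spacing, origin)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(vol: Volume, path, format: str | None = None) -> None:
    """Write a volume to NIfTI or MetaImage.

    CT volumes are stored as 32-bit float (HU are often non-integral after
    filtering), masks as unsigned 8-bit, probability maps as 32-bit float.
    """
    _format_for_path(path, format)
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise IOError(f"directory does not exist: {parent}")
    if isinstance(vol, BinaryMask):
        arr = vol.voxels.astype(np.uint8)
    else:
        arr = vol.voxels.astype(np.float32)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as e:  # pragma: no cover
        raise IOError(f"could not write image {path}: {e}") from e


def median_filter_3(vol: CTVolume) -> CTVolume:
    """3x3x3 median filter with nearest-edge replication at the borders.

    Applied to both scans of a pair immediately before any attenuation-threshold
    classification; knocks out single-voxel noise spikes while preserving the
    piecewise structure of parenchyma.
    """
    if min(vol.shape) < 3:
        raise ValueError(f"volume too small for a 3x3x3 filter: shape {vol.shape}")
    filtered = ndimage.median_filter(vol.voxels, size=3, mode="nearest")
    return vol.with_voxels(filtered)
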