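"""Automated lung-field extraction from a chest CT volume.

The strategy is the classic connected-component one: threshold low-attenuation
voxels, discard exterior air (low-attenuation regions face-connected to the
volume border), keep the up-to-two largest remaining components above a minimum
volume, close small gaps morphologically, and finally enforce the rule that no
lung voxel may have HU > 0 (dense tissue, e.g. nodules or vessels caught by the
closing, is never parenchyma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, EmptySegmentationError
from .volume import BinaryMask, CTVolume


@dataclass(frozen=True)
class LungSegmentationConfig:
    air_threshold: float = -300.0  # HU below which a voxel is a lung/air candidate
    min_component_volume: float = 50.0  # mL
    closing_radius: int = 2  # voxels

    def __post_init__(self):
        if self.air_threshold >= 0:
            raise ValueError("air_threshold must be negative (HU)")
        if self.min_component_volume <= 0:
            raise ValueError("min_component_volume must be positive")


def _ball(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1, 1), dtype=bool)
    L = np.arange(-radius, radius + 1)
    zz, yy, xx = np.meshgrid(L, L, L, indexing="ij")
    return zz * zz + yy * yy + xx * xx <= radius * radius


def segment_lungs(vol: CTVolume, cfg: LungSegmentationConfig | None = None) -> BinaryMask:
    """Segment the lung fields of a CT volume.

    Raises EmptySegmentationError when no candidate component reaches
    ``cfg.min_component_volume``.
    """
    cfg = cfg or LungSegmentationConfig()
    low = vol.voxels < cfg.air_threshold

    # face connectivity: exterior air is any low-attenuation region touching a border
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(low, structure=structure)
    if n == 0:
        raise EmptySegmentationError("no voxels below the air threshold")

    border_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            idx = [slice(None)] * 3
            idx[axis] = sl
            border_labels.update(np.unique(labels[tuple(idx)]))
    border_labels.discard(0)

    counts = np.bincount(labels.ravel())
    counts[0] = 0
    for lb in border_labels:
        counts[lb] = 0

    min_voxels = cfg.min_component_volume / vol.voxel_volume_ml
    candidates = [lb for lb in np.argsort(counts)[::-1][:2] if counts[lb] >= min_voxels]
    if not candidates:
        raise EmptySegmentationError(
            f"no interior low-attenuation component of at least "
            f"{cfg.min_component_volume} mL"
        )

    mask = np.isin(labels, candidates)
    if cfg.closing_radius >= 1:
        mask = ndimage.binary_closing(
            mask, structure=_ball(cfg.closing_radius), border_value=0
        )
    # exclusion applied last so closing cannot re-admit dense voxels
    mask &= vol.voxels <= 0
    return BinaryMask(mask, vol.spacing, vol.origin)


class MaskStatistics:
    """Summary statistics of a CT volume restricted to a mask.

    Percentiles use linear interpolation between order statistics."""

    def __init__(self, vol: CTVolume, mask: BinaryMask):
        vol.require_same_geometry(mask, "volume and mask")
        values = vol.voxels[mask.as_bool()]
        if values.size == 0:
            raise EmptyMaskError("mask is empty")
        self._values = np.asarray(values, dtype=np.float64)
        self.voxel_count = int(values.size)
        self.volume_ml = self.voxel_count * vol.voxel_volume_ml
        self.mean_hu = float(self._values.mean())

    def percentile(self, q) -> float:
        return float(np.percentile(self._values, q))

    def __repr__(self):
        return (
            f"MaskStatistics(n={self.voxel_count}, volume={self.volume_ml:.1f} mL, "
            f"mean={self.mean_hu:.1f} HU)"
        )


def mask_statistics(vol: CTVolume, mask: BinaryMask) -> MaskStatistics:
    """Voxel count, physical volume, mean HU and a percentile function."""
    return MaskStatistics(vol, mask)
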