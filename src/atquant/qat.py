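"""Threshold-based quantitative air trapping (QAT).

Two quantifiers operate on the median-filtered expiratory scan restricted to the
lung mask:

* the static threshold at -856 HU, the conventional cutoff for gas trapping on
  expiratory CT, and
* the Personalized Threshold Method (PTM), which derives a subject-specific
  threshold from the inspiratory lung histogram and its deflation response:

      T = X - (1 - D/343) * (X - Y) / 3

  with X and Y the 90th and 50th percentile of inspiratory lung attenuation and
  D the deflation response of the 90th percentile.  The constant 343 HU acts as
  a full-deflation normalizer: when the 90th percentile rises by 343 HU on
  expiration the correction term vanishes and T falls back to X.

QAT is the percentage of lung voxels classified as trapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, GeometryError
from .lungseg import mask_statistics
from .volume import BinaryMask, CTVolume

log = logging.getLogger(__name__)

STATIC_THRESHOLD_HU = -856.0

#: Allowed conventions for the deflation-response difference D.
D_CONVENTIONS = ("exp_minus_insp", "insp_minus_exp")


@dataclass(frozen=True)
class PTMResult:
    """Percentile statistics and personalized threshold for one scan pair."""

    X: float  # 90th percentile of inspiratory lung HU
    Y: float  # 50th percentile of inspiratory lung HU
    D: float  # deflation response of the 90th percentile
    T: float  # personalized threshold
    d_convention: str = "exp_minus_insp"

    def __post_init__(self):
        if self.Y > self.X + 1e-9:
            raise ValueError(f"50th percentile Y={self.Y} exceeds 90th X={self.X}")


@dataclass(frozen=True)
class QATResult:
    method: str  # {'static856', 'ptm', 'dn'}
    threshold_used: float | None  # HU, or None for the network method
    at_voxels: int
    lung_voxels: int

    @property
    def qat_percent(self) -> float:
        return 100.0 * self.at_voxels / self.lung_voxels


def ptm_threshold(X: float, Y: float, D: float) -> float:
    """Personalized threshold T = X - (1 - D/343)(X - Y)/3, unclamped."""
    if Y > X:
        raise ValueError(f"requires Y <= X, got Y={Y}, X={X}")
    return X - (1.0 - D / 343.0) * (X - Y) / 3.0


def compute_ptm(
    insp: CTVolume,
    exp: CTVolume,
    insp_mask: BinaryMask,
    exp_mask: BinaryMask,
    d_convention: str = "exp_minus_insp",
) -> PTMResult:
    """Derive the personalized threshold from a (median-filtered) scan pair.

    Both volumes are expected to have been passed through ``median_filter_3``
    already; percentiles are taken over masked voxels only.
    """
    if d_convention not in D_CONVENTIONS:
        raise ValueError(f"d_convention must be one of {D_CONVENTIONS}")
    insp_stats = mask_statistics(insp, insp_mask)
    exp_stats = mask_statistics(exp, exp_mask)
    X = insp_stats.percentile(90)
    Y = insp_stats.percentile(50)
    p90_exp = exp_stats.percentile(90)
    if d_convention == "exp_minus_insp":
        D = p90_exp - X
    else:
        D = X - p90_exp
    if not 0.0 <= D <= 343.0:
        log.warning(
            "deflation response D=%.1f HU outside [0, 343]; threshold extrapolated", D
        )
    return PTMResult(X=X, Y=Y, D=D, T=ptm_threshold(X, Y, D), d_convention=d_convention)


def at_map(exp: CTVolume, mask: BinaryMask, T: float) -> BinaryMask:
    """Binary air-trapping map: voxel = 1 iff inside the mask and HU strictly < T."""
    exp.require_same_geometry(mask, "expiratory volume and lung mask")
    at = (exp.voxels < T) & mask.as_bool()
    return mask.with_voxels(at)


def qat_from_map(at: BinaryMask, lung: BinaryMask) -> QATResult:
    """QAT percentage from an AT map normalized to the whole-lung voxel count."""
    at.require_same_geometry(lung, "AT map and lung mask")
    if lung.count == 0:
        raise EmptyMaskError("lung mask is empty")
    if np.any(at.as_bool() & ~lung.as_bool()):
        raise GeometryError("AT map contains voxels outside the lung mask")
    return QATResult(
        method="unspecified",
        threshold_used=None,
        at_voxels=at.count,
        lung_voxels=lung.count,
    )


def _qat_with_threshold(exp: CTVolume, mask: BinaryMask, T: float, method: str) -> QATResult:
    at = at_map(exp, mask, T)
    base = qat_from_map(at, mask)
    return QATResult(
        method=method,
        threshold_used=T,
        at_voxels=base.at_voxels,
        lung_voxels=base.lung_voxels,
    )


def qat_static856(exp: CTVolume, mask: BinaryMask) -> QATResult:
    """QAT with the accepted static threshold of -856 HU."""
    return _qat_with_threshold(exp, mask, STATIC_THRESHOLD_HU, "static856")


def qat_ptm(
    insp: CTVolume,
    exp: CTVolume,
    insp_mask: BinaryMask,
    exp_mask: BinaryMask,
    d_convention: str = "exp_minus_insp",
) -> tuple[QATResult, PTMResult]:
    """Personalized-threshold QAT on a median-filtered scan pair."""
    ptm = compute_ptm(insp, exp, insp_mask, exp_mask, d_convention)
    return _qat_with_threshold(exp, exp_mask, ptm.T, "ptm"), ptm
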