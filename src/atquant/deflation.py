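"""Simulation of expiratory deflation levels via Jacobian-determinant scaling.

A deformable registration of the inspiratory onto the expiratory scan yields a
per-voxel Jacobian determinant J, interpreted here as the local
inspiration-to-expiration volume-contraction factor (>= 1 in normally
deflating lung).  Intermediate deflation levels are produced by scaling the
volume change linearly,

    J* = 1 + beta * (J - 1),    beta in [0, 1],

and applying the scaled determinant to the registered (warped) inspiratory
scan so that tissue mass is preserved: air-referenced density HU + 1000 is
multiplied by J*.  beta = 0 reproduces the warped inspiratory scan (no
deflation) and beta = 1 the fully deflated expiration.  A ``literal`` mode
multiplies raw HU instead of air-referenced density, for fidelity to the
published expression Exp* = J* . Exp.

The module consumes displacement fields from any registration provider; it
implements no registration itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FoldingError
from .qat import QATResult, at_map, qat_from_map, qat_ptm, qat_static856
from .volume import BinaryMask, CTVolume, HU_MAX, HU_MIN, Volume, median_filter_3

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class JacobianMap(Volume):
    """Per-voxel volume-change factors; strictly positive."""

    def __post_init__(self):
        arr = np.asarray(self.voxels, dtype=np.float64)
        if arr.size and arr.min() <= 0:
            raise ValueError("Jacobian determinant must be strictly positive")
        object.__setattr__(self, "voxels", arr)
        super().__post_init__()

    def with_voxels(self, voxels: np.ndarray) -> "JacobianMap":
        return JacobianMap(voxels, self.spacing, self.origin)


@dataclass(frozen=True)
class DisplacementField:
    """A displacement field in expiratory geometry.

    ``vectors`` has shape (z, y, x, 3) with components ordered (dz, dy, dx) in
    millimetres; ``spacing`` is (z, y, x) mm/voxel.
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.vectors, dtype=np.float64)
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError(f"expected (z, y, x, 3) vectors, got {arr.shape}")
        object.__setattr__(self, "vectors", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))


@dataclass
class DeflationCurve:
    """QAT per deflation fraction beta for one scan pair and several methods."""

    betas: list[float]
    qat: dict[str, list[float]] = field(default_factory=dict)  # method -> QAT(beta) %
    thresholds: dict[str, list[float | None]] = field(default_factory=dict)

    def __post_init__(self):
        b = list(self.betas)
        if b != sorted(b, reverse=True) or not b or abs(b[0] - 1.0) > 1e-12:
            raise ValueError("betas must be sorted descending starting at 1.0")

    @property
    def delta_qat(self) -> dict[str, list[float]]:
        """QAT(beta) - QAT(1) per method."""
        return {m: [q - qs[0] for q in qs] for m, qs in self.qat.items()}


def scale_jacobian(J: JacobianMap, beta: float) -> JacobianMap:
    """J* = 1 + beta (J - 1); exact at both endpoints."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    return J.with_voxels(1.0 + beta * (J.voxels - 1.0))


def simulate_expiration(
    warped_insp: CTVolume,
    J: JacobianMap,
    beta: float,
    mode: str = "physical",
) -> CTVolume:
    """Simulated expiratory scan at deflation fraction ``beta``.

    ``physical`` (default) scales air-referenced density, preserving tissue
    mass:  HU* = J* (HU + 1000) - 1000.  ``literal`` multiplies raw HU by J*
    as in the published expression.  Output is clamped to the valid HU range.
    """
    if mode not in ("physical", "literal"):
        raise ValueError(f"mode must be 'physical' or 'literal', got {mode!r}")
    warped_insp.require_same_geometry(J, "warped inspiratory volume and Jacobian")
    js = scale_jacobian(J, beta).voxels
    if mode == "physical":
        hu = js * (warped_insp.voxels.astype(np.float64) + 1000.0) - 1000.0
    else:
        hu = js * warped_insp.voxels.astype(np.float64)
    n_clamped = int(np.count_nonzero((hu < HU_MIN) | (hu > HU_MAX)))
    if n_clamped:
        log.info("simulate_expiration: clamped %d voxels to HU range", n_clamped)
    return CTVolume(np.clip(hu, HU_MIN, HU_MAX), warped_insp.spacing, warped_insp.origin)


def jacobian_from_field(field: DisplacementField) -> JacobianMap:
    """Determinant of (I + displacement gradient) per voxel, central differences.

    Gradients are taken with respect to physical (mm) coordinates.  Raises
    FoldingError when any determinant is non-positive.
    """
    u = field.vectors
    grads = np.empty(u.shape[:3] + (3, 3), dtype=np.float64)
    for comp in range(3):
        gz, gy, gx = np.gradient(u[..., comp], *field.spacing)
        grads[..., comp, 0] = gz
        grads[..., comp, 1] = gy
        grads[..., comp, 2] = gx
    grads[..., 0, 0] += 1.0
    grads[..., 1, 1] += 1.0
    grads[..., 2, 2] += 1.0
    det = np.linalg.det(grads)
    n_folded = int(np.count_nonzero(det <= 0))
    if n_folded:
        raise FoldingError(n_folded)
    return JacobianMap(det, field.spacing, field.origin)


def deflation_curve(
    warped_insp: CTVolume,
    insp_filtered: CTVolume,
    insp_mask: BinaryMask,
    exp_mask: BinaryMask,
    J: JacobianMap,
    betas,
    methods,
    model=None,
    mode: str = "physical",
    d_convention: str = "exp_minus_insp",
    recompute_ptm_threshold: bool = True,
) -> DeflationCurve:
    """QAT-vs-deflation sensitivity curve for one phantom/scan pair.

    For each beta the expiratory scan is simulated, median filtered, and every
    requested method's QAT computed on it.  ``methods`` draw from
    {'static856', 'ptm', 'dn'}; 'dn' requires a trained ``model``.  The PTM
    threshold is by default re-derived per beta from the simulated pair (a
    per-scan personalized threshold); with ``recompute_ptm_threshold=False``
    the baseline (beta = 1) threshold is frozen and reused.
    """
    betas = sorted({float(b) for b in betas}, reverse=True)
    if not betas or betas[0] != 1.0:
        betas = [1.0] + [b for b in betas if b != 1.0]
    if any(b <= 0 or b > 1 for b in betas):
        raise ValueError("betas must lie in (0, 1]")
    unknown = set(methods) - {"static856", "ptm", "dn"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if "dn" in methods and model is None:
        raise ValueError("method 'dn' requires a trained model")

    curve = DeflationCurve(betas=betas, qat={m: [] for m in methods},
                           thresholds={m: [] for m in methods})
    frozen_T = None
    for beta in betas:
        sim = simulate_expiration(warped_insp, J, beta, mode=mode)
        sim_f = median_filter_3(sim)
        for m in methods:
            if m == "static856":
                res = qat_static856(sim_f, exp_mask)
            elif m == "ptm":
                if recompute_ptm_threshold or frozen_T is None:
                    res, ptm = qat_ptm(
                        insp_filtered, sim_f, insp_mask, exp_mask, d_convention
                    )
                    if frozen_T is None:
                        frozen_T = ptm.T
                else:
                    at = at_map(sim_f, exp_mask, frozen_T)
                    base = qat_from_map(at, exp_mask)
                    res = QATResult("ptm", frozen_T, base.at_voxels, base.lung_voxels)
            else:
                from .dn import predict  # local import to avoid cycle

                _, _, res = predict(model, sim_f, exp_mask)
            curve.qat[m].append(res.qat_percent)
            curve.thresholds[m].append(res.threshold_used)
    return curve
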