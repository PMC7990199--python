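"""Synthetic paired inspiratory/expiratory CT phantom with analytic ground truth.

The phantom emulates the data regime of paired pediatric chest CT with mosaic
attenuation on expiration:

* an ellipsoidal soft-tissue body (~30 HU) surrounded by exterior air;
* two ellipsoidal lungs whose inspiratory attenuation is a smooth parenchymal
  texture around -850 HU plus scanner noise;
* patchy air-trapping (AT) regions drawn by thresholding a correlated Gaussian
  random field inside the lungs to hit a target volume fraction;
* a per-voxel contraction field J that takes the normal-lung value J_n outside
  the AT patches and the near-unity value J_at inside them (trapped lung fails
  to deflate), smoothly blended;
* an expiratory scan whose air-referenced density is J times the inspiratory
  density (mass-preserving by construction), so AT regions retain near-
  inspiratory attenuation while normal lung densifies;
* an axial displacement field whose discrete Jacobian determinant reproduces
  the stored contraction field: u_z is the cumulative integral of (J - 1) dz,
  so det(I + grad u) = 1 + du_z/dz regardless of in-plane variation.

The stored "analytic" Jacobian is defined through the same central-difference
stencil used by ``jacobian_from_field`` (a [1,2,1]/4 smoothing along z of the
raw contraction field), so the numerical operator recovers it to float
rounding rather than to truncation error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid

from .deflation import DisplacementField, JacobianMap
from .errors import AtquantError
from .volume import BinaryMask, CTVolume


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (40, 96, 96)  # (z, y, x) voxels
    spacing_mm: float = 2.0  # isotropic
    body_hu: float = 30.0
    lung_hu_mean: float = -850.0
    lung_hu_sd: float = 40.0  # parenchymal texture spread
    j_normal: float = 1.6  # contraction of normally deflating lung
    j_at: float = 1.05  # contraction of trapped lung
    at_fraction: float = 15.0  # % of lung volume
    at_corr_mm: float = 28.0  # correlation length of the AT blob field
    texture_corr_mm: float = 2.6  # correlation length of parenchymal texture
    noise_sd: float = 15.0  # additive scanner noise, HU
    residual_sd: float = 3.0  # model residual between exp and mass-scaled insp
    j_smooth_mm: float = 0.5  # blending width of the contraction field
    seed: int = 0

    def __post_init__(self):
        if not (self.j_normal > self.j_at >= 1.0):
            raise ValueError("requires j_normal > j_at >= 1")
        if not 0.0 <= self.at_fraction <= 60.0:
            raise ValueError("AT fraction must lie in [0, 60] %")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.spacing_mm,) * 3


@dataclass(frozen=True)
class PhantomPair:
    """One synthetic subject at one timepoint, with full ground truth."""

    insp: CTVolume
    exp: CTVolume
    warped_insp: CTVolume
    insp_mask: BinaryMask
    exp_mask: BinaryMask
    at_truth: BinaryMask
    field: DisplacementField
    jacobian: JacobianMap
    spec: PhantomSpec
    subject: str = "S00"
    timepoint: int = 0
    # noiseless references for analytic checks
    insp_clean: np.ndarray | None = None
    exp_clean: np.ndarray | None = None

    @property
    def at_fraction_truth(self) -> float:
        """Ground-truth AT volume as % of lung volume."""
        return 100.0 * self.at_truth.count / self.exp_mask.count


def _ellipsoid(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _correlated_field(rng, shape, sigma_vox) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)


def _z_stencil(J: np.ndarray) -> np.ndarray:
    """[1,2,1]/4 smoothing along z with the one-sided edge rule of np.gradient."""
    out = np.empty_like(J)
    out[1:-1] = 0.25 * (J[:-2] + 2.0 * J[1:-1] + J[2:])
    out[0] = 0.5 * (J[0] + J[1])
    out[-1] = 0.5 * (J[-1] + J[-2])
    return out


def generate_phantom(
    spec: PhantomSpec, subject: str = "S00", timepoint: int = 0,
    lung_scale: float = 1.0, at_quantile_field: np.ndarray | None = None,
) -> PhantomPair:
    """Generate one paired phantom.

    ``lung_scale`` mildly rescales the lung ellipsoids (anatomic variation);
    ``at_quantile_field`` allows a caller (the suite) to reuse one blob field
    across timepoints so progression grows existing AT regions.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    dz = spec.spacing_mm

    body = _ellipsoid(shape, (shape[0] // 2, shape[1] // 2, shape[2] // 2),
                      (shape[0] * 0.6, shape[1] * 0.44, shape[2] * 0.48))
    cz, cy = shape[0] // 2, int(shape[1] * 0.48)
    semi = (shape[0] * 0.325 * lung_scale, shape[1] * 0.25 * lung_scale,
            shape[2] * 0.135 * lung_scale)
    left = _ellipsoid(shape, (cz, cy, int(shape[2] * 0.28)), semi)
    right = _ellipsoid(shape, (cz, cy, int(shape[2] * 0.72)), semi)
    lung = left | right
    if not lung.any():
        raise AtquantError("degenerate phantom spec: empty lung")

    # AT ground truth: thresholded correlated field, exact in-lung quantile
    sigma_blob = spec.at_corr_mm / (2.0 * dz)
    if at_quantile_field is None:
        at_quantile_field = _correlated_field(rng, shape, sigma_blob)
    else:
        rng.standard_normal(shape)  # keep downstream draws aligned
    at_truth = np.zeros(shape, dtype=bool)
    if spec.at_fraction > 0:
        for _ in range(5):
            thr = np.percentile(at_quantile_field[lung], 100.0 - spec.at_fraction)
            at_truth = (at_quantile_field > thr) & lung
            got = 100.0 * at_truth.sum() / lung.sum()
            if abs(got - spec.at_fraction) <= 2.0:
                break
            at_quantile_field = _correlated_field(rng, shape, sigma_blob)
        else:
            raise AtquantError(
                f"could not hit AT fraction {spec.at_fraction}% +- 2 pp "
                f"with correlation length {spec.at_corr_mm} mm"
            )

    # contraction field: J_at in trapped patches, J_normal elsewhere in lung
    j_raw = np.ones(shape)
    j_raw[lung] = spec.j_normal
    j_raw[at_truth] = spec.j_at
    j_sm = ndimage.gaussian_filter(j_raw, spec.j_smooth_mm / dz)
    j_eff = _z_stencil(j_sm)

    # displacement consistent with the contraction: axial, cumulative integral
    u = np.zeros(shape + (3,))
    u[..., 0] = cumulative_trapezoid(j_sm - 1.0, dx=dz, axis=0, initial=0.0)
    field = DisplacementField(u, spacing=spec.spacing)
    jacobian = JacobianMap(j_eff, spacing=spec.spacing)

    # clean inspiratory scan with parenchymal texture
    texture = _correlated_field(rng, shape, spec.texture_corr_mm / (2.0 * dz))
    tex_in_lung = texture[lung]
    texture = (texture - tex_in_lung.mean()) / max(tex_in_lung.std(), 1e-9)
    insp_clean = np.full(shape, -1000.0)
    insp_clean[body] = spec.body_hu
    insp_clean[lung] = spec.lung_hu_mean + spec.lung_hu_sd * texture[lung]

    # scans: warped inspiration carries its own scan noise; expiration is the
    # mass-scaled warped inspiration plus a small model residual
    noise_insp = rng.normal(0.0, spec.noise_sd, shape)
    noise_warp = rng.normal(0.0, spec.noise_sd, shape)
    resid = rng.normal(0.0, spec.residual_sd, shape)
    insp = CTVolume(insp_clean + noise_insp, spec.spacing)
    warped = CTVolume(insp_clean + noise_warp, spec.spacing)
    exp_clean = j_eff * (insp_clean + 1000.0) - 1000.0
    exp_hu = j_eff * (warped.voxels + 1000.0) - 1000.0 + resid
    exp = CTVolume(exp_hu, spec.spacing)

    mask = BinaryMask(lung, spec.spacing)
    return PhantomPair(
        insp=insp,
        exp=exp,
        warped_insp=warped,
        insp_mask=mask,
        exp_mask=mask,
        at_truth=BinaryMask(at_truth, spec.spacing),
        field=field,
        jacobian=jacobian,
        spec=spec,
        subject=subject,
        timepoint=timepoint,
        insp_clean=insp_clean,
        exp_clean=exp_clean,
    )


def phantom_suite(
    n_subjects: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    timepoints: int = 4,
) -> list[PhantomPair]:
    """A longitudinal cohort of phantoms.

    Each subject has a fixed anatomy and AT blob field; the AT volume fraction
    grows across timepoints (progression), so within-subject fractions are
    non-decreasing by construction.  Baseline fractions and per-interval
    increments vary across subjects (~5-30 % overall), as do noise level and
    lung size.  Deterministic per (base_spec, seed).
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    pairs = []
    for s in range(n_subjects):
        f0 = float(master.uniform(5.0, 15.0))
        step = float(master.uniform(1.5, 4.0))
        noise = float(master.uniform(0.8, 1.2) * base.noise_sd)
        scale = float(master.uniform(0.92, 1.05))
        subj_seed = int(master.integers(0, 2**31 - 1))
        # one blob field per subject so progression grows existing patches
        blob_rng = np.random.default_rng(subj_seed)
        sigma_blob = base.at_corr_mm / (2.0 * base.spacing_mm)
        blob_field = _correlated_field(blob_rng, base.shape, sigma_blob)
        for t in range(timepoints):
            spec = replace(
                base,
                at_fraction=min(f0 + t * step, 60.0),
                noise_sd=noise,
                seed=int((subj_seed + 7919 * t) % (2**31 - 1)),
            )
            pairs.append(
                generate_phantom(
                    spec,
                    subject=f"S{s:02d}",
                    timepoint=t,
                    lung_scale=scale,
                    at_quantile_field=blob_field,
                )
            )
    return pairs
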