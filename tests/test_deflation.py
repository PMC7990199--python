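import numpy as np
import pytest

from atquant.deflation import (
    DisplacementField,
    JacobianMap,
    jacobian_from_field,
    scale_jacobian,
    simulate_expiration,
)
from atquant.errors import FoldingError, GeometryError
from atquant.volume import CTVolume


def _random_positive_jacobian(rng, shape=(6, 7, 8)):
    return JacobianMap(np.exp(rng.normal(0.2, 0.2, shape)))


class TestScaleJacobian:
    def test_beta_zero_gives_identity_map(self, rng):
        J = _random_positive_jacobian(rng)
        np.testing.assert_array_equal(scale_jacobian(J, 0.0).voxels, np.ones(J.shape))

    def test_beta_one_returns_j_bit_exact(self, rng):
        J = _random_positive_jacobian(rng)
        np.testing.assert_array_equal(scale_jacobian(J, 1.0).voxels, J.voxels)

    def test_midpoint_arithmetic(self):
        J = JacobianMap(np.full((3, 3, 3), 1.5))
        assert scale_jacobian(J, 0.5).voxels[0, 0, 0] == pytest.approx(1.25)

    def test_linear_in_beta(self, rng):
        J = _random_positive_jacobian(rng)
        a, b = 0.3, 0.8
        mid = scale_jacobian(J, (a + b) / 2).voxels
        avg = (scale_jacobian(J, a).voxels + scale_jacobian(J, b).voxels) / 2
        np.testing.assert_allclose(mid, avg, rtol=1e-12)

    def test_beta_out_of_range_rejected(self, rng):
        J = _random_positive_jacobian(rng)
        for beta in (-0.1, 1.1):
            with pytest.raises(ValueError):
                scale_jacobian(J, beta)


class TestSimulateExpiration:
    def test_beta_zero_reproduces_warped_inspiration(self, rng):
        warped = CTVolume(rng.normal(-800, 60, (5, 6, 7)))
        J = _random_positive_jacobian(rng, (5, 6, 7))
        out = simulate_expiration(warped, J, 0.0)
        np.testing.assert_array_equal(out.voxels, warped.voxels)

    def test_pointwise_density_scaling(self):
        warped = CTVolume(np.full((3, 3, 3), -900.0))
        J = JacobianMap(np.full((3, 3, 3), 1.3))
        out = simulate_expiration(warped, J, 1.0, mode="physical")
        assert out.voxels[1, 1, 1] == pytest.approx(-870.0)

    def test_literal_mode_multiplies_raw_hu(self):
        warped = CTVolume(np.full((3, 3, 3), -900.0))
        J = JacobianMap(np.full((3, 3, 3), 1.1))
        out = simulate_expiration(warped, J, 1.0, mode="literal")
        assert out.voxels[0, 0, 0] == pytest.approx(-990.0)

    def test_full_deflation_matches_phantom_expiration(self, default_pair):
        p = default_pair
        sim = simulate_expiration(p.warped_insp, p.jacobian, 1.0)
        lung = p.exp_mask.as_bool()
        mad = np.abs(sim.voxels[lung] - p.exp.voxels[lung]).mean()
        assert mad <= 5.0

    def test_mass_conservation_identity(self, rng):
        """In physical mode the operation is exactly multiplicative in density."""
        warped = CTVolume(rng.normal(-700, 80, (6, 6, 6)))
        J = _random_positive_jacobian(rng, (6, 6, 6))
        beta = 0.7
        out = simulate_expiration(warped, J, beta)
        js = 1 + beta * (J.voxels - 1)
        lhs = (out.voxels.astype(np.float64) + 1000).sum()
        rhs = (js * (warped.voxels.astype(np.float64) + 1000)).sum()
        # exact up to float32 storage of the output volume
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_mean_lung_hu_monotone_in_beta(self, default_pair):
        p = default_pair
        lung = p.exp_mask.as_bool()
        means = [
            simulate_expiration(p.warped_insp, p.jacobian, b).voxels[lung].mean()
            for b in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))

    def test_geometry_mismatch_rejected(self, rng):
        warped = CTVolume(np.zeros((4, 4, 4)))
        J = JacobianMap(np.ones((5, 5, 5)))
        with pytest.raises(GeometryError):
            simulate_expiration(warped, J, 0.5)


class TestJacobianFromField:
    def test_zero_field_gives_identity(self):
        f = DisplacementField(np.zeros((5, 6, 7, 3)), spacing=(2, 2, 2))
        np.testing.assert_allclose(jacobian_from_field(f).voxels, 1.0)

    def test_uniform_contraction_has_closed_form_determinant(self):
        # x -> 0.9 x  =>  u = -0.1 x, det = 0.9^3 in the interior
        shape = (8, 8, 8)
        spacing = (1.5, 1.5, 1.5)
        coords = np.meshgrid(
            *[np.arange(s) * sp for s, sp in zip(shape, spacing)], indexing="ij"
        )
        u = np.stack([-0.1 * c for c in coords], axis=-1)
        det = jacobian_from_field(DisplacementField(u, spacing)).voxels
        np.testing.assert_allclose(det[1:-1, 1:-1, 1:-1], 0.729, rtol=1e-10)

    def test_phantom_analytic_jacobian_recovered(self, default_pair):
        p = default_pair
        det = jacobian_from_field(p.field).voxels
        rel = np.abs(det - p.jacobian.voxels) / p.jacobian.voxels
        interior = rel[1:-1, 1:-1, 1:-1]
        assert interior.max() <= 0.01

    def test_folding_field_rejected(self):
        shape = (6, 6, 6)
        u = np.zeros(shape + (3,))
        # strong compression along z reverses orientation
        u[..., 0] = -2.5 * np.arange(shape[0])[:, None, None]
        with pytest.raises(FoldingError):
            jacobian_from_field(DisplacementField(u, (1, 1, 1)))

    def test_jacobian_map_requires_positive_values(self):
        with pytest.raises(ValueError):
            JacobianMap(np.zeros((3, 3, 3)))
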