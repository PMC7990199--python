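import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atquant.errors import EmptyMaskError, GeometryError
from atquant.qat import (
    at_map,
    compute_ptm,
    ptm_threshold,
    qat_from_map,
    qat_ptm,
    qat_static856,
)
from atquant.volume import BinaryMask, CTVolume, median_filter_3


class TestPTMThreshold:
    @pytest.mark.parametrize(
        "X,Y,D,expected",
        [
            (-750.0, -850.0, 343.0, -750.0),  # correction vanishes at D=343
            (-750.0, -850.0, 0.0, -750.0 - 100.0 / 3.0),
            (-700.0, -700.0, 120.0, -700.0),  # degenerate X=Y
        ],
    )
    def test_known_values(self, X, Y, D, expected):
        assert ptm_threshold(X, Y, D) == pytest.approx(expected, abs=1e-9)

    def test_rejects_inverted_percentiles(self):
        with pytest.raises(ValueError):
            ptm_threshold(-800.0, -700.0, 100.0)

    @given(
        Y=st.floats(-1000, -400),
        dx=st.floats(0, 300),
        D=st.floats(-200, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_symbolic_expansion(self, Y, dx, D):
        """Affine in each argument: T = X - (X-Y)/3 + D(X-Y)/1029."""
        X = Y + dx
        expected = X - (X - Y) / 3.0 + D * (X - Y) / 1029.0
        assert ptm_threshold(X, Y, D) == pytest.approx(expected, rel=1e-12, abs=1e-9)


class TestComputePTM:
    def test_identical_scans_give_zero_deflation_response(self, rng):
        arr = rng.normal(-800, 50, (10, 10, 10))
        vol = CTVolume(arr)
        mask = BinaryMask(np.ones((10, 10, 10)))
        ptm = compute_ptm(vol, vol, mask, mask)
        assert ptm.D == pytest.approx(0.0, abs=1e-9)
        assert ptm.T == pytest.approx(ptm.X - (ptm.X - ptm.Y) / 3.0, abs=1e-6)

    def test_single_voxel_masks_degenerate(self):
        arr = np.full((3, 3, 3), -640.0)
        vol = CTVolume(arr)
        mask = np.zeros((3, 3, 3))
        mask[1, 1, 1] = 1
        ptm = compute_ptm(vol, vol, BinaryMask(mask), BinaryMask(mask))
        assert ptm.X == ptm.Y == -640.0
        assert ptm.T == pytest.approx(-640.0)

    def test_gaussian_phantom_matches_closed_form_percentiles(self, rng):
        """Insp ~ N(-850,40), exp ~ N(-700,40): D ~ 150, T between Y and X."""
        n = (40, 50, 50)
        insp = CTVolume(rng.normal(-850, 40, n))
        exp = CTVolume(rng.normal(-700, 40, n))
        mask = BinaryMask(np.ones(n))
        ptm = compute_ptm(insp, exp, mask, mask)
        z90 = 1.2815515655446004
        assert ptm.X == pytest.approx(-850 + z90 * 40, abs=2.0)
        assert ptm.Y == pytest.approx(-850, abs=2.0)
        assert ptm.D == pytest.approx(150.0, abs=3.0)
        assert ptm.Y < ptm.T < ptm.X

    def test_d_convention_switch_flips_sign(self, rng):
        n = (10, 12, 12)
        insp = CTVolume(rng.normal(-850, 30, n))
        exp = CTVolume(rng.normal(-700, 30, n))
        mask = BinaryMask(np.ones(n))
        a = compute_ptm(insp, exp, mask, mask, "exp_minus_insp")
        b = compute_ptm(insp, exp, mask, mask, "insp_minus_exp")
        assert a.D == pytest.approx(-b.D)

    def test_empty_mask_rejected(self):
        vol = CTVolume(np.zeros((4, 4, 4)))
        empty = BinaryMask(np.zeros((4, 4, 4)))
        with pytest.raises(EmptyMaskError):
            compute_ptm(vol, vol, empty, empty)


class TestATMap:
    def test_strict_inequality_at_threshold(self):
        arr = np.full((4, 4, 4), -856.0)
        mask = BinaryMask(np.ones((4, 4, 4)))
        at = at_map(CTVolume(arr), mask, -856.0)
        assert at.count == 0

    def test_all_below_threshold_fills_mask(self):
        arr = np.full((4, 4, 4), -857.0)
        mask = BinaryMask(np.ones((4, 4, 4)))
        at = at_map(CTVolume(arr), mask, -856.0)
        np.testing.assert_array_equal(at.voxels, mask.voxels)

    def test_matches_elementwise_oracle(self, rng):
        arr = rng.normal(-820, 60, (8, 9, 10))
        vol = CTVolume(arr)
        mask = BinaryMask(rng.random((8, 9, 10)) > 0.3)
        at = at_map(vol, mask, -830.0)
        expected = (vol.voxels < -830.0) & mask.as_bool()
        np.testing.assert_array_equal(at.as_bool(), expected)

    def test_geometry_mismatch_rejected(self):
        vol = CTVolume(np.zeros((4, 4, 4)))
        mask = BinaryMask(np.ones((5, 5, 5)))
        with pytest.raises(GeometryError):
            at_map(vol, mask, -856.0)


class TestQAT:
    def test_fraction_arithmetic(self):
        lung = np.zeros((5, 5, 5))
        lung.ravel()[:100] = 1
        at = np.zeros((5, 5, 5))
        at.ravel()[:25] = 1
        res = qat_from_map(BinaryMask(at), BinaryMask(lung))
        assert res.qat_percent == pytest.approx(25.0)

    def test_empty_and_full_extremes(self):
        lung = BinaryMask(np.ones((4, 4, 4)))
        empty = BinaryMask(np.zeros((4, 4, 4)))
        assert qat_from_map(empty, lung).qat_percent == 0.0
        assert qat_from_map(lung, lung).qat_percent == 100.0

    def test_at_outside_lung_rejected(self):
        lung = np.zeros((4, 4, 4))
        lung[0, 0, 0] = 1
        at = np.zeros((4, 4, 4))
        at[1, 1, 1] = 1
        with pytest.raises(GeometryError):
            qat_from_map(BinaryMask(at), BinaryMask(lung))
        with pytest.raises(EmptyMaskError):
            qat_from_map(BinaryMask(at), BinaryMask(np.zeros((4, 4, 4))))

    def test_static856_uniform_lungs(self):
        mask = BinaryMask(np.ones((4, 4, 4)))
        assert qat_static856(CTVolume(np.full((4, 4, 4), -700.0)), mask).qat_percent == 0.0
        assert qat_static856(CTVolume(np.full((4, 4, 4), -900.0)), mask).qat_percent == 100.0

    def test_static856_recovers_bimodal_phantom_fraction(self, rng):
        """AT at -900 HU, normal at -700 HU: QAT within 1 pp of truth."""
        n = (20, 30, 30)
        frac = 0.3
        at = rng.random(n) < frac
        arr = np.where(at, -900.0, -700.0)
        res = qat_static856(CTVolume(arr), BinaryMask(np.ones(n)))
        truth = 100.0 * at.sum() / at.size
        assert res.qat_percent == pytest.approx(truth, abs=1.0)

    def test_qat_monotone_in_threshold(self, rng):
        arr = rng.normal(-800, 70, (10, 12, 12))
        vol = CTVolume(arr)
        mask = BinaryMask(np.ones((10, 12, 12)))
        qats = [
            qat_from_map(at_map(vol, mask, t), mask).qat_percent
            for t in np.linspace(-950, -650, 13)
        ]
        assert all(a <= b for a, b in zip(qats, qats[1:]))

    def test_ptm_less_strict_than_static_on_default_phantom(self, default_pair):
        p = default_pair
        insp_f = median_filter_3(p.insp)
        exp_f = median_filter_3(p.exp)
        res_ptm, ptm = qat_ptm(insp_f, exp_f, p.insp_mask, p.exp_mask)
        res_856 = qat_static856(exp_f, p.exp_mask)
        assert ptm.T > -856.0
        assert res_ptm.qat_percent >= res_856.qat_percent
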