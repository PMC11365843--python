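"""Volumetry: change formulas, soft volumes, calibration fits, pair driver."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bvlkit.registration.fields import DeformationField
from bvlkit.study import measure_with_truth
from bvlkit.volumetry import (
    CalibrationError,
    CalibrationParams,
    DegenerateInputError,
    PairVolumes,
    compute_pair_from_volumes,
    delta_bw,
    delta_fw,
    distortion_correct,
    fit_rescale_regression,
    fit_tiv_regression,
    mask_volume,
    rescale,
    soft_volume,
    symmetric_mean,
)


class TestChangeFormulas:
    @pytest.mark.parametrize("bl,warped,expected", [
        (1000.0, 990.0, -1.0), (1000.0, 1000.0, 0.0), (800.0, 808.0, 1.0),
    ])
    def test_forward_change(self, bl, warped, expected):
        assert delta_fw(bl, warped) == pytest.approx(expected)

    @pytest.mark.parametrize("fu,warped,expected", [
        (990.0, 1000.0, -1.0), (1000.0, 1000.0, 0.0), (505.0, 500.0, 1.0),
    ])
    def test_backward_change_uses_warped_denominator(self, fu, warped, expected):
        assert delta_bw(fu, warped) == pytest.approx(expected)

    @pytest.mark.parametrize("fw,bw,expected", [(-1.0, -1.0, -1.0), (-0.8, -1.2, -1.0), (0, 0, 0)])
    def test_symmetric_mean(self, fw, bw, expected):
        assert symmetric_mean(fw, bw) == expected

    @pytest.mark.parametrize("dbpv,dtiv,expected", [
        (1.0, 1.0, 0.05),   # published slope leaves 5% of a common-mode change
        (0.7, 0.0, 0.7),    # no apparent TIV change: nothing to correct
        (0.95, 1.0, 0.0),   # pure-distortion pair fully corrected
    ])
    def test_distortion_correction_slope_only(self, dbpv, dtiv, expected):
        cal = CalibrationParams()  # m_tiv = 0.95, intercept unused
        assert distortion_correct(dbpv, dtiv, cal) == pytest.approx(expected)

    @pytest.mark.parametrize("res,expected", [(-0.30, -1.0), (0.0, 0.0), (0.15, 0.5)])
    def test_rescaling(self, res, expected):
        assert rescale(res, CalibrationParams()) == pytest.approx(expected)

    def test_zero_denominators_raise(self):
        with pytest.raises(DegenerateInputError):
            delta_fw(0.0, 1.0)
        with pytest.raises(DegenerateInputError):
            delta_bw(1.0, 0.0)
        with pytest.raises(CalibrationError):
            CalibrationParams(m_siena=0.0)


class TestVolumes:
    def test_cube_mask_volume(self):
        mask = np.zeros((20, 20, 20), dtype=np.uint8)
        mask[5:15, 5:15, 5:15] = 1
        assert mask_volume(mask, 1.0) == 1000.0
        one = np.zeros((4, 4, 4), dtype=np.uint8)
        one[1, 2, 3] = 1
        assert mask_volume(one, 1.5**3) == pytest.approx(1.5**3)
        with pytest.raises(DegenerateInputError):
            mask_volume(np.zeros((4, 4, 4)))

    def test_soft_volume_identity_and_half_shift_conservation(self):
        from bvlkit.registration.fields import warp

        mask = np.zeros((24, 24, 24), dtype=np.float32)
        mask[6:18, 6:18, 6:18] = 1.0
        assert soft_volume(mask, 1.0) == mask_volume(mask, 1.0)
        disp = np.zeros(mask.shape + (3,), dtype=np.float32)
        disp[..., 1] = 0.5
        shifted = warp(mask, DeformationField(disp))
        assert soft_volume(shifted, 1.0) == pytest.approx(soft_volume(mask, 1.0), rel=1e-4)

    def test_soft_volume_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            soft_volume(np.full((3, 3, 3), -0.5))


def _vols(bpv_bl, bpv_fu, bpv_fb, bpv_bf, tiv=50000.0):
    return PairVolumes(bpv_bl, bpv_fu, bpv_fb, bpv_bf, tiv, tiv, tiv, tiv)


class TestPairDriver:
    def test_identical_volumes_give_all_zero(self):
        res = compute_pair_from_volumes(_vols(40000, 40000, 40000, 40000),
                                        CalibrationParams())
        assert all(v == 0 for v in res.to_dict().values())

    @given(
        bpv=st.floats(3e4, 6e4),
        d1=st.floats(-0.03, 0.03),
        d2=st.floats(-0.03, 0.03),
        m_siena=st.floats(0.2, 1.5),
    )
    def test_final_estimate_identity_holds_exactly(self, bpv, d1, d2, m_siena):
        """The final estimate equals half the per-direction sum over the
        rescaling slope, bit-exact, for any admissible volume combination."""
        cal = CalibrationParams(m_siena=m_siena)
        vols = _vols(bpv, bpv * (1 + d2), bpv * (1 + d1), bpv / (1 + d2))
        res = compute_pair_from_volumes(vols, cal)
        assert res.bvl == 0.5 * (res.bvl_fw + res.bvl_bw) / cal.m_siena

    def test_sanity_gate_rejects_gross_warp_failure(self):
        with pytest.raises(DegenerateInputError, match="deviates"):
            compute_pair_from_volumes(_vols(40000, 40000, 28000, 40000),
                                      CalibrationParams())

    def test_oracle_fields_recover_truth(self, small_pair, unit_cal):
        res = measure_with_truth(small_pair, unit_cal)
        assert res.bvl == pytest.approx(-2.0, abs=0.15)
        # TIV boundary discretization dominates at 32^3 (the field vanishes
        # on the TIV surface but not just inside it)
        assert res.dtiv == pytest.approx(0.0, abs=0.6)


class TestCalibrationFits:
    def test_noiseless_lines_to_machine_precision(self):
        x = np.linspace(-2, 2, 40)
        m, c, _, _ = fit_tiv_regression(0.95 * x - 0.23, x)
        assert m == pytest.approx(0.95, abs=1e-12)
        assert c == pytest.approx(-0.23, abs=1e-12)
        m, c, _, _ = fit_rescale_regression(0.30 * x - 0.01, x)
        assert m == pytest.approx(0.30, abs=1e-12)
        assert c == pytest.approx(-0.01, abs=1e-12)

    def test_noisy_slope_within_ci(self, rng):
        x = rng.normal(0, 0.5, 200)
        y = 0.9 * x + rng.normal(0, 0.05, 200)
        m, _, ci, _ = fit_tiv_regression(y, x)
        assert ci[0] <= 0.9 <= ci[1]
        assert m == pytest.approx(0.9, abs=0.05)

    def test_degenerate_predictor_raises(self):
        with pytest.raises(DegenerateInputError):
            fit_tiv_regression([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        with pytest.raises(DegenerateInputError):
            fit_rescale_regression([1.0, 2.0], [1.0, 2.0])

    def test_calibration_yaml_roundtrip(self, tmp_path):
        cal = CalibrationParams(m_tiv=0.9, c_tiv=-0.1, m_siena=0.4, c_siena=0.02,
                                provenance="refit:test")
        cal.to_yaml(tmp_path / "cal.yaml")
        back = CalibrationParams.from_yaml(tmp_path / "cal.yaml")
        assert back == cal
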