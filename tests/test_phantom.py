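"""Phantom generator: geometry, exact truth, determinism, cohort output."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bvlkit.phantom import (
    AtrophyParameterizationError,
    AtrophySpec,
    PhantomSizingError,
    PhantomSpec,
    generate_cohort,
    make_baseline,
    make_followup,
    make_pair,
)
from bvlkit.volumetry import mask_volume


def analytic_ellipsoid_volume(radii):
    return 4.0 / 3.0 * np.pi * np.prod(np.asarray(radii, dtype=float))


class TestBaseline:
    def test_tiv_mask_matches_analytic_volume_and_converges(self):
        spec = PhantomSpec(tiv_radii_mm=(20.0, 24.0, 20.0))
        _, _, tiv = make_baseline(spec)
        analytic = analytic_ellipsoid_volume(spec.tiv_radii_mm)
        err64 = abs(mask_volume(tiv) - analytic) / analytic
        assert err64 < 0.02
        # refining the voxel grid shrinks the discretization error
        fine = dataclasses.replace(spec, grid_size=(128,) * 3, voxel_mm=0.5)
        _, _, tiv_fine = make_baseline(fine)
        err128 = abs(mask_volume(tiv_fine) - analytic) / analytic
        assert err128 < err64

    def test_deterministic_given_seed(self, small_spec):
        spec = dataclasses.replace(small_spec, noise_sigma=3.0, seed=42)
        a, _, _ = make_baseline(spec)
        b, _, _ = make_baseline(spec)
        assert np.array_equal(a.data, b.data)
        c, _, _ = make_baseline(dataclasses.replace(spec, seed=43))
        assert not np.array_equal(a.data, c.data)

    def test_zero_ventricle_gives_solid_parenchyma(self, small_spec):
        spec = dataclasses.replace(small_spec, ventricle_radii_mm=(0.0, 0.0, 0.0))
        _, par, tiv = make_baseline(spec)
        assert np.array_equal(par.data, tiv.data)

    def test_oversized_skull_raises_naming_axis(self):
        spec = PhantomSpec(grid_size=(32, 64, 64))
        with pytest.raises(PhantomSizingError, match="axis x"):
            make_baseline(spec)

    def test_volume_carries_voxel_metadata(self, small_spec):
        vol, _, _ = make_baseline(small_spec)
        assert np.allclose(vol.voxel_mm, small_spec.voxel_mm)


class TestFollowup:
    def test_identity_atrophy_reproduces_baseline_bitwise(self, small_spec):
        bl, _, _ = make_baseline(small_spec)
        fu, truth = make_followup(bl, small_spec, AtrophySpec(0.0, "radial", 1.0))
        assert np.array_equal(fu.data, bl.data)
        assert np.all(truth.true_field.disp == 0)
        assert np.all(truth.true_field_bw.disp == 0)

    @pytest.mark.parametrize("bvl", [-1.0, -2.0, 1.0])
    def test_exact_truth_volume_ratio(self, small_spec, bvl):
        bl, _, _ = make_baseline(small_spec)
        _, truth = make_followup(bl, small_spec, AtrophySpec(bvl, "radial", 1.0))
        ratio = truth.bpv_fu_mm3 / truth.bpv_bl_mm3
        assert ratio == pytest.approx(1.0 + bvl / 100.0, abs=2e-6)

    def test_rasterized_masks_track_truth(self):
        pair = make_pair(PhantomSpec(), AtrophySpec(-2.0, "radial", 1.0))
        v_bl = mask_volume(pair.truth.masks["bl_parenchyma"])
        v_fu = mask_volume(pair.truth.masks["fu_parenchyma"])
        assert 100 * (v_fu / v_bl - 1) == pytest.approx(-2.0, abs=0.25)

    def test_distortion_scales_bpv_and_tiv_identically(self):
        spec = PhantomSpec()
        bl, _, _ = make_baseline(spec)
        _, truth = make_followup(bl, spec, AtrophySpec(0.0, "radial", 1.005))
        expected = 100 * (1.005**3 - 1)
        assert 100 * (truth.tiv_fu_mm3 / truth.tiv_bl_mm3 - 1) == pytest.approx(expected, abs=0.05)
        assert 100 * (truth.bpv_fu_mm3 / truth.bpv_bl_mm3 - 1) == pytest.approx(expected, abs=0.05)
        # and the rasterized masks agree to within boundary discretization
        v = mask_volume(truth.masks["fu_tiv"]) / mask_volume(truth.masks["bl_tiv"])
        assert 100 * (v - 1) == pytest.approx(expected, abs=0.15)

    def test_uniform_scale_mode_truth(self, small_spec):
        bl, _, _ = make_baseline(small_spec)
        _, truth = make_followup(bl, small_spec, AtrophySpec(-3.0, "uniform-scale", 1.0))
        assert truth.bpv_fu_mm3 / truth.bpv_bl_mm3 == pytest.approx(0.97, abs=1e-9)
        assert truth.tiv_fu_mm3 == pytest.approx(truth.tiv_bl_mm3)

    def test_radial_mode_requires_proportional_ventricle(self, small_spec):
        spec = dataclasses.replace(small_spec, ventricle_radii_mm=(2.0, 2.0, 2.0))
        bl, _, _ = make_baseline(spec)
        with pytest.raises(AtrophyParameterizationError, match="proportional"):
            make_followup(bl, spec, AtrophySpec(-1.0, "radial", 1.0))

    def test_unreachable_bvl_raises(self, small_spec):
        bl, _, _ = make_baseline(small_spec)
        with pytest.raises(ValueError, match="unreachable"):
            make_followup(bl, small_spec, AtrophySpec(9.0, "radial", 1.0))

    def test_volume_conservation_null_pair(self, small_spec):
        pair = make_pair(small_spec, AtrophySpec(0.0, "radial", 1.0))
        v_bl = mask_volume(pair.truth.masks["bl_parenchyma"])
        v_fu = mask_volume(pair.truth.masks["fu_parenchyma"])
        assert v_fu == v_bl


class TestCohort:
    def test_cohort_reproducible_and_complete(self, tmp_path, small_spec):
        t1 = generate_cohort(4, tmp_path / "a", seed=7, spec=small_spec)
        t2 = generate_cohort(4, tmp_path / "b", seed=7, spec=small_spec)
        pd.testing.assert_frame_equal(t1, t2)
        assert (tmp_path / "a" / "truth.csv").exists()
        for pid in t1.pair_id:
            assert (tmp_path / "a" / f"{pid}_bl.nii.gz").exists()
            assert (tmp_path / "a" / f"{pid}_fu_tiv.nii.gz").exists()

    def test_pinned_ranges_pin_truth(self, tmp_path, small_spec):
        t = generate_cohort(3, tmp_path / "c", seed=1, bvl_range=(0.0, 0.0),
                            distortion_range=(1.0, 1.0), spec=small_spec)
        assert (t.true_bvl_percent == 0).all()
        assert (t.distortion_scale == 1).all()

    def test_uniform_bvl_sampling_mean(self, tmp_path, small_spec):
        t = generate_cohort(50, tmp_path / "d", seed=3, bvl_range=(-2.0, 0.0),
                            spec=small_spec, save_masks=False)
        se = 2.0 / np.sqrt(12) / np.sqrt(50)
        assert abs(t.true_bvl_percent.mean() - (-1.0)) < 3 * se

    def test_rejects_empty_cohort(self, tmp_path):
        with pytest.raises(ValueError):
            generate_cohort(0, tmp_path / "e")
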