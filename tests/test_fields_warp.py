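"""Displacement fields, pull-warping and the Jacobian-integration oracle."""

import numpy as np
import pytest

from bvlkit.phantom import make_baseline
from bvlkit.registration.fields import (
    DeformationField,
    radial_atrophy_field,
    radial_profile_amplitude,
    uniform_scale_field,
    warp,
)
from bvlkit.volumetry import jacobian_integration, mask_volume, soft_volume


@pytest.fixture
def par_mask():
    from bvlkit.phantom import PhantomSpec

    _, par, _ = make_baseline(PhantomSpec())
    return par


class TestWarp:
    def test_zero_field_is_identity_bitwise(self, rng):
        data = rng.random((12, 14, 10)).astype(np.float32)
        out = warp(data, DeformationField.zero(data.shape))
        assert np.array_equal(out, data)

    def test_integer_shift_is_exact_voxel_shift(self, rng):
        data = rng.random((16, 16, 16)).astype(np.float32)
        disp = np.zeros(data.shape + (3,), dtype=np.float32)
        disp[..., 0] = 2.0  # pull from 2 voxels ahead along axis 0
        out = warp(data, DeformationField(disp))
        assert np.array_equal(out[:-2], data[2:])
        assert np.all(out[-2:] == 0)  # zero padding outside

    def test_uniform_scale_soft_volume_ratio(self, par_mask):
        f = uniform_scale_field(par_mask.shape, 0.99, "pull")
        v0 = mask_volume(par_mask)
        v1 = soft_volume(np.clip(warp(par_mask.data.astype(np.float32), f), 0, 1), 1.0)
        assert v1 / v0 == pytest.approx(0.99**3, rel=0.003)

    def test_shape_mismatch_raises(self, rng):
        data = rng.random((8, 8, 8)).astype(np.float32)
        with pytest.raises(ValueError, match="grid mismatch"):
            warp(data, DeformationField.zero((8, 8, 10)))


class TestDeformationField:
    def test_rejects_nonfinite_and_bad_shape(self):
        bad = np.zeros((4, 4, 4, 3), dtype=np.float32)
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            DeformationField(bad)
        with pytest.raises(ValueError, match="displacements"):
            DeformationField(np.zeros((4, 4, 4, 2)))

    def test_nifti_roundtrip(self, tmp_path, rng):
        f = DeformationField(rng.normal(size=(6, 6, 6, 3)).astype(np.float32), "BL->FU")
        f.save(tmp_path / "f.nii.gz")
        g = DeformationField.load(tmp_path / "f.nii.gz", "BL->FU")
        assert np.allclose(f.disp, g.disp)


class TestJacobianIntegration:
    def test_zero_field_zero_change(self, par_mask):
        assert jacobian_integration(DeformationField.zero(par_mask.shape), par_mask) == 0.0

    @pytest.mark.parametrize("scale", [0.99, 1.01])
    def test_uniform_scale_closed_form(self, par_mask, scale):
        f = uniform_scale_field(par_mask.shape, scale, "forward")
        ji = jacobian_integration(f, par_mask)
        assert ji == pytest.approx(100 * (scale**3 - 1), abs=0.05)

    def test_radial_field_matches_target(self, par_mask):
        from bvlkit.phantom import PhantomSpec

        spec = PhantomSpec()
        f = radial_atrophy_field(spec.grid_size, np.asarray(spec.tiv_radii_mm), 0.25,
                                 -1.0, "forward")
        assert jacobian_integration(f, par_mask) == pytest.approx(-1.0, abs=0.1)

    def test_folding_field_warns(self, par_mask, rng):
        disp = rng.normal(0, 3.0, par_mask.shape + (3,)).astype(np.float32)
        with pytest.warns(RuntimeWarning, match="non-positive"):
            jacobian_integration(DeformationField(disp), par_mask)


class TestRadialProfile:
    @pytest.mark.parametrize("bvl", [-0.5, -2.0, 1.0])
    def test_amplitude_hits_target_volume_change(self, bvl):
        kappa = 0.25
        amp = radial_profile_amplitude(kappa, bvl)
        gk = kappa + amp * kappa * (1 - kappa**2) ** 2
        shell_ratio = (1 - gk**3) / (1 - kappa**3)
        assert shell_ratio == pytest.approx(1 + bvl / 100, abs=1e-12)

    def test_folding_request_raises(self):
        # a tiny ventricle cannot absorb a large loss without the profile folding
        with pytest.raises(ValueError, match="folds"):
            radial_profile_amplitude(0.1, -9.0)

    def test_unreachable_expansion_raises(self):
        # growth that would require negative ventricle volume
        with pytest.raises(ValueError, match="unreachable"):
            radial_profile_amplitude(0.25, 9.0)

    def test_pull_and_forward_fields_are_inverse_maps(self):
        # composing pull after forward sampling positions returns the start
        shape = (32, 32, 32)
        fwd = radial_atrophy_field(shape, (12.0, 12.0, 12.0), 0.25, -2.0, "forward")
        pull = radial_atrophy_field(shape, (12.0, 12.0, 12.0), 0.25, -2.0, "pull")
        grid = np.stack(np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                                    indexing="ij"), axis=-1)
        # phi(x) then phi^-1 at those (off-grid) positions: check on-grid proxy
        # |u_pull(phi(x)) + u_fwd(x)| small where displacements are smooth
        phi = grid + fwd.disp
        inner = np.linalg.norm(grid - np.asarray(shape) / 2, axis=-1) < 8
        from scipy.ndimage import map_coordinates

        pull_at_phi = np.stack([
            map_coordinates(pull.disp[..., c], np.moveaxis(phi, -1, 0), order=1)
            for c in range(3)
        ], axis=-1)
        resid = np.linalg.norm(pull_at_phi + fwd.disp, axis=-1)[inner]
        assert resid.max() < 0.05
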