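"""Preprocessing: reslicing, head cropping, rigid halfway registration."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

from bvlkit.phantom import PhantomSpec, make_baseline
from bvlkit.preprocess import (
    SegmentationFailureError,
    crop_head,
    estimate_rigid,
    head_crop_box,
    normalize_crop,
    reslice_isotropic,
    rigid_register_halfway,
)
from bvlkit.volume import RigidTransform, Volume3D


@pytest.fixture(scope="module")
def phantom64():
    vol, _, _ = make_baseline(PhantomSpec())
    return vol


class TestReslice:
    def test_canonical_isotropic_input_unchanged(self, phantom64):
        out = reslice_isotropic(phantom64, 1.0)
        assert np.array_equal(out.data, phantom64.data)
        assert np.allclose(out.affine, phantom64.affine)

    def test_downsampling_preserves_integral(self):
        spec = PhantomSpec(grid_size=(44, 44, 44), voxel_mm=0.5,
                           skull_radii_mm=(8.0, 9.0, 8.0), tiv_radii_mm=(6.0, 7.2, 6.0),
                           ventricle_radii_mm=(1.5, 1.8, 1.5))
        vol, _, _ = make_baseline(spec)
        out = reslice_isotropic(vol, 1.0)
        integral_in = vol.data.sum() * vol.voxel_volume_mm3
        integral_out = out.data.sum() * out.voxel_volume_mm3
        assert integral_out == pytest.approx(integral_in, rel=0.01)
        assert np.allclose(out.voxel_mm, 1.0)

    def test_axis_permuted_input_is_pure_permutation(self, phantom64):
        perm_affine = phantom64.affine[:, [1, 0, 2, 3]]
        permuted = Volume3D(np.transpose(phantom64.data, (1, 0, 2)).copy(), perm_affine)
        out = reslice_isotropic(permuted, 1.0)
        assert np.array_equal(out.data, phantom64.data)


class TestCrop:
    def test_full_skull_retained(self, phantom64):
        cropped = crop_head(phantom64, (56, 60, 60))
        thr = 0.5 * PhantomSpec().tissue_intensities[1]
        n_before = int((phantom64.data > thr).sum())
        n_after = int((cropped.data > thr).sum())
        assert n_after == n_before

    def test_identity_when_shape_matches_grid(self, phantom64):
        box = head_crop_box(phantom64, phantom64.shape)
        cropped = crop_head(phantom64, phantom64.shape)
        assert np.all(box == 0)
        assert np.array_equal(cropped.data, phantom64.data)

    def test_empty_volume_raises(self):
        with pytest.raises(SegmentationFailureError):
            crop_head(Volume3D(np.zeros((32, 32, 32))), (16, 16, 16))


def _move_rigidly(vol: Volume3D, rot_deg, axis, t_mm):
    """Move rigidly about the grid center; returns the world-frame transform."""
    rot = Rotation.from_rotvec(np.radians(rot_deg) * np.asarray(axis)).as_matrix()
    center = (np.asarray(vol.shape) - 1) / 2
    offset = center - rot.T @ center + rot.T @ (-np.asarray(t_mm))
    moved = affine_transform(vol.data.astype(np.float64), rot.T, offset=offset, order=1)
    t_world = center - rot @ center + np.asarray(t_mm)
    return Volume3D(moved.astype(np.float32), vol.affine), RigidTransform(rot, t_world)


class TestRigidHalfway:
    def test_known_motion_recovered(self, phantom64):
        fu, true_t = _move_rigidly(phantom64, 5.0, [0, 0, 1], [3.0, 0.0, 0.0])
        est = estimate_rigid(phantom64, fu)
        resid = est.compose(true_t.inverse())
        assert resid.rotation_angle_deg() < 0.2
        assert np.linalg.norm(resid.translation) < 0.2

    def test_halfway_crops_align(self, phantom64):
        fu, _ = _move_rigidly(phantom64, 5.0, [0, 0, 1], [3.0, 0.0, 0.0])
        pair = rigid_register_halfway(phantom64, fu)
        dyn = float(phantom64.data.max() - phantom64.data.min())
        mad = float(np.abs(pair.bl_crop.data - pair.fu_crop.data).mean())
        assert mad < 0.02 * dyn

    def test_identical_inputs_near_identity(self, phantom64):
        pair = rigid_register_halfway(phantom64, phantom64.copy())
        assert pair.half_fu.rotation_angle_deg() < 0.1
        assert np.linalg.norm(pair.half_fu.translation) < 0.1
        assert np.abs(pair.bl_crop.data - phantom64.data).mean() < 0.01 * phantom64.data.max()

    def test_pure_translation_splits_into_half_translations(self, phantom64):
        fu, _ = _move_rigidly(phantom64, 0.0, [0, 0, 1], [4.0, 0.0, 0.0])
        pair = rigid_register_halfway(phantom64, fu)
        assert pair.half_fu.translation[0] == pytest.approx(2.0, abs=0.2)
        assert pair.half_bl.translation[0] == pytest.approx(-2.0, abs=0.2)

    def test_sqrt_transform_composes_exactly(self):
        t = RigidTransform(Rotation.from_euler("xyz", [10, -4, 7], degrees=True).as_matrix(),
                           [3.0, -1.0, 2.5])
        h = t.sqrt()
        hh = h.compose(h)
        assert np.allclose(hh.rotation, t.rotation, atol=1e-12)
        assert np.allclose(hh.translation, t.translation, atol=1e-12)


class TestNormalize:
    def test_foreground_zero_mean_unit_sd(self, phantom64):
        out = normalize_crop(phantom64)
        data = out.data
        ref = np.percentile(phantom64.data, 99.9)
        fg = phantom64.data > 0.05 * ref
        assert abs(float(data[fg].mean())) < 1e-5
        assert float(data[fg].std()) == pytest.approx(1.0, abs=1e-5)

    def test_empty_crop_raises(self):
        with pytest.raises(SegmentationFailureError):
            normalize_crop(Volume3D(np.zeros((16, 16, 16))))
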