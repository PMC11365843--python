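"""Registration engine: loss terms, U-Net contracts, training, backends."""

import dataclasses

import numpy as np
import pytest

from bvlkit.phantom import AtrophySpec, make_pair
from bvlkit.preprocess import normalize_crop
from bvlkit.registration.backends import InstanceOptBackend, OracleBackend, predict_field
from bvlkit.registration.fields import warp
from bvlkit.registration.losses import (
    local_ncc,
    registration_loss,
    smoothness_loss_grad,
)
from bvlkit.registration.train import train_registration
from bvlkit.registration.unet import RegistrationConfig, ShapeError, UNet3D, build_unet
from bvlkit.volumetry import soft_volume

TINY = RegistrationConfig(unet_channels=(4, 6), flow_level=1, epochs=2,
                          gaussian_noise_sigma=0.0, seed=5)


@pytest.fixture(scope="module")
def small_crops():
    from tests.conftest import SMALL_SPEC

    pair = make_pair(SMALL_SPEC, AtrophySpec(-3.0, "radial", 1.0, seed=11))
    return normalize_crop(pair.bl).data, normalize_crop(pair.fu).data, pair


class TestLoss:
    def test_perfect_match_scores_minus_one(self, small_crops):
        a, _, _ = small_crops
        zero = np.zeros(a.shape + (3,), dtype=np.float32)
        assert registration_loss(a, a, zero, smoothness_weight=1.0) == pytest.approx(-1.0)
        # flat windows are handled by the epsilon, never NaN
        flat = np.zeros_like(a)
        assert np.isfinite(registration_loss(flat, flat, zero))

    def test_constant_field_has_zero_smoothness_penalty(self, rng):
        const = np.broadcast_to(np.float32([0.4, -1.0, 2.0]), (8, 8, 8, 3)).copy()
        loss, grad = smoothness_loss_grad(const, weight=1.0)
        assert loss == 0.0
        assert np.all(grad == 0)

    def test_rough_field_penalized_more_than_smooth(self, rng):
        from scipy.ndimage import gaussian_filter

        rough = rng.normal(size=(12, 12, 12, 3)).astype(np.float32)
        smooth = np.stack([gaussian_filter(rough[..., c], 2.0) for c in range(3)], axis=-1)
        assert smoothness_loss_grad(rough, 1.0)[0] > smoothness_loss_grad(smooth, 1.0)[0]

    def test_ncc_decreases_with_misalignment(self, small_crops):
        a, _, _ = small_crops
        assert local_ncc(a, a) > local_ncc(np.roll(a, 2, axis=0), a)


class TestUNet:
    def test_zero_initialized_flow_and_shape_contract(self, small_crops):
        a, b, _ = small_crops
        model = build_unet(TINY)
        flow = model.forward(a, b)
        assert flow.shape == a.shape + (3,)
        assert np.all(flow == 0)  # zero-init head => identity transform

    def test_indivisible_shape_raises(self):
        model = build_unet(TINY)
        bad = np.zeros((30, 32, 32), dtype=np.float32)
        with pytest.raises(ShapeError, match="divisible"):
            model.forward(bad, bad)

    def test_checkpoint_roundtrip(self, tmp_path, small_crops):
        a, b, _ = small_crops
        model = build_unet(TINY)
        for p in model.parameters():
            p.value += 0.01 * np.random.default_rng(0).normal(size=p.value.shape).astype(np.float32)
        model.save(tmp_path / "w.npz")
        clone = UNet3D.load(tmp_path / "w.npz")
        assert clone.config == model.config
        assert np.array_equal(clone.forward(a, b), model.forward(a, b))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(ncc_window=8).validate()
        with pytest.raises(ValueError):
            RegistrationConfig(smoothness_weight=-1).validate()
        with pytest.raises(ValueError):
            RegistrationConfig(epochs=0).validate()
        with pytest.raises(ValueError):
            RegistrationConfig(flow_level=3).validate()


class TestTraining:
    def test_fixed_seed_reproduces_weights(self, small_crops):
        a, b, _ = small_crops
        m1, h1 = train_registration([(a, b), (b, a)], TINY)
        m2, h2 = train_registration([(a, b), (b, a)], TINY)
        assert h1 == h2
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(p1.value, p2.value)

    def test_loss_improves_on_desk_cohort(self, trained_setup):
        history = trained_setup["history"]
        assert history[-1] < history[0]
        assert history[-1] < 0.5 * history[0]

    def test_needs_at_least_two_pairs(self, small_crops):
        a, b, _ = small_crops
        with pytest.raises(ValueError):
            train_registration([(a, b)], TINY)


class TestBackends:
    def test_oracle_backend_returns_exact_truth_field(self, small_crops):
        a, b, pair = small_crops
        backend = OracleBackend(a, b, pair.truth.true_field, pair.truth.true_field_bw)
        f = predict_field(backend, a, b)
        assert f is pair.truth.true_field
        assert predict_field(backend, b, a) is pair.truth.true_field_bw
        with pytest.raises(ValueError):
            backend.predict(a * 2, b)

    def test_instance_optimization_moves_toward_truth(self, small_crops):
        a, b, pair = small_crops
        backend = InstanceOptBackend(iters=60, lr=0.2)
        f = predict_field(backend, a, b)
        par = pair.truth.masks["bl_parenchyma"].data.astype(np.float32)
        v0 = float(par.sum())
        v1 = soft_volume(np.clip(warp(par, f), 0, 1), 1.0)
        change = 100 * (v1 / v0 - 1)
        true_change = 100 * (pair.truth.bpv_fu_mm3 / pair.truth.bpv_bl_mm3 - 1)
        assert change < -0.5  # contraction detected
        assert abs(change - true_change) < abs(0.0 - true_change)  # better than identity

    def test_trained_backend_symmetric_self_registration(self, trained_setup):
        from bvlkit.phantom import PhantomSpec

        backend = trained_setup["backend"]
        pair = make_pair(dataclasses.replace(PhantomSpec(), seed=99),
                         AtrophySpec(0.0, "radial", 1.0))
        a = normalize_crop(pair.bl).data
        f = predict_field(backend, a, a)
        assert float(np.abs(f.disp).mean()) == 0.0
        # antisymmetry of the symmetric backend under input swap
        b = normalize_crop(pair.fu).data
        assert np.allclose(predict_field(backend, a, b).disp,
                           -predict_field(backend, b, a).disp)
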