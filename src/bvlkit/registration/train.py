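"""Unsupervised training of the registration U-Net.

Each step draws a BL/FU crop pair, optionally augments it (left-right flip
and rotation applied identically to both crops; Gaussian noise added
independently to each crop), randomly interchanges which crop is source and
which is target, predicts the displacement field and minimizes the local-NCC
+ smoothness loss with Adam.  Gradients are accumulated over ``batch_size``
pairs per optimizer step.  Fixed seed implies a reproducible loss trajectory
and final weights.
"""

from __future__ import annotations

import logging
import time

import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

from .losses import registration_loss_grad
from .nn import Adam
from .unet import RegistrationConfig, UNet3D, build_unet

log = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    pass


def _random_rotation(vols, max_deg: float, rng: np.random.Generator):
    """Rotate all volumes by one random rotation about the grid center."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_deg, max_deg))
    mat = Rotation.from_rotvec(axis * angle).as_matrix()
    center = (np.asarray(vols[0].shape) - 1) / 2.0
    offset = center - mat @ center
    return [
        affine_transform(v, mat, offset=offset, order=1, mode="constant", cval=0.0)
        for v in vols
    ]


def _augment(src: np.ndarray, tgt: np.ndarray, cfg: RegistrationConfig,
             rng: np.random.Generator):
    if cfg.flip and rng.random() < 0.5:
        src = src[::-1].copy()
        tgt = tgt[::-1].copy()
    if cfg.rotation_deg > 0:
        src, tgt = _random_rotation([src, tgt], cfg.rotation_deg, rng)
    if cfg.gaussian_noise_sigma > 0:
        src = src + rng.normal(0.0, cfg.gaussian_noise_sigma, src.shape).astype(np.float32)
        tgt = tgt + rng.normal(0.0, cfg.gaussian_noise_sigma, tgt.shape).astype(np.float32)
    return np.asarray(src, np.float32), np.asarray(tgt, np.float32)


def train_registration(pairs, config: RegistrationConfig, model: UNet3D | None = None,
                       checkpoint_path=None, callback=None):
    """Train (or continue training) the U-Net on a cohort of crop pairs.

    Parameters
    ----------
    pairs
        Sequence of ``(crop_a, crop_b)`` float arrays on a common grid,
        already intensity-normalized.
    config
        :class:`RegistrationConfig`; augmentation follows its flags.
    model
        Optional pre-built network (weights are updated in place).

    Returns ``(model, history)`` where history is the per-epoch mean loss.
    """
    config.validate()
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("training needs at least 2 pairs")
    model = model or build_unet(config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng([config.seed, 29])
    history = []
    for epoch in range(config.epochs):
        t0 = time.time()
        order = rng.permutation(len(pairs))
        losses = []
        opt.zero_grad()
        in_batch = 0
        for step, idx in enumerate(order):
            a, b = pairs[idx]
            src, tgt = (a, b)
            if config.direction_interchange and rng.random() < 0.5:
                src, tgt = tgt, src
            src, tgt = _augment(np.asarray(src, np.float32), np.asarray(tgt, np.float32),
                                config, rng)
            flow = model.forward(src, tgt)
            loss, dflow = registration_loss_grad(
                src, tgt, flow, smoothness_weight=config.smoothness_weight,
                win=config.ncc_window, magnitude_weight=config.magnitude_weight,
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, pair index {int(idx)}"
                )
            model.backward(dflow / config.batch_size)
            losses.append(loss)
            in_batch += 1
            if in_batch == config.batch_size or step == len(order) - 1:
                if config.grad_clip > 0:
                    gnorm = np.sqrt(sum(float((p.grad ** 2).sum())
                                        for p in model.parameters()))
                    if gnorm > config.grad_clip:
                        scale = config.grad_clip / gnorm
                        for p in model.parameters():
                            p.grad *= scale
                opt.step()
                opt.zero_grad()
                in_batch = 0
        mean_loss = float(np.mean(losses))
        history.append(mean_loss)
        log.info("epoch %d/%d: loss %.5f (%.1fs)", epoch + 1, config.epochs,
                 mean_loss, time.time() - t0)
        if callback is not None:
            callback(epoch, mean_loss)
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return model, history
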