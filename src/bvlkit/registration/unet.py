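"""Small 3D U-Net predicting a dense displacement field from a crop pair.

Encoder-decoder with skip connections in the style of unsupervised
registration networks: the two preprocessed crops are concatenated as a
2-channel input, the output is a 3-channel displacement field (voxels) at
crop resolution.  The final convolution is zero-initialized so the untrained
network predicts the identity transform.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np

from .nn import AvgPool2, Conv3d, LeakyReLU, UpsampleNearest2

log = logging.getLogger(__name__)


class ShapeError(ValueError):
    pass


@dataclass(frozen=True)
class RegistrationConfig:
    """Hyperparameters of the registration network and its training.

    Desk-scale defaults (64^3 crops, small channel widths, tens of epochs)
    train on a CPU in minutes; larger published-scale settings (176x208x208,
    350 epochs, batch 2, Adam lr 1e-4) remain reachable through these keys.
    """

    unet_channels: tuple[int, ...] = (8, 16, 16)
    flow_level: int = 2
    """Resolution level of the flow head: 0 = full crop resolution, k = field
    predicted on the 2^k-coarser grid (displacement values in full-res
    voxels, nearest-upsampled).  The coarse default suits the smooth fields
    of interest here and avoids the full-resolution decoder dominating CPU
    cost."""
    ncc_window: int = 9
    smoothness_weight: float = 1.0
    magnitude_weight: float = 0.03
    """Weight of the weak zero-displacement prior (see losses)."""
    epochs: int = 40
    batch_size: int = 2
    learning_rate: float = 5e-3
    grad_clip: float = 1.0
    """Global gradient-norm clip per optimizer step (0 disables)."""
    flip: bool = True
    rotation_deg: float = 0.0
    gaussian_noise_sigma: float = 0.03
    direction_interchange: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.smoothness_weight < 0:
            raise ValueError("smoothness_weight must be >= 0")
        if self.ncc_window % 2 == 0 or self.ncc_window < 3:
            raise ValueError("ncc_window must be odd and >= 3")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.unet_channels:
            raise ValueError("unet_channels must be non-empty")
        if not (0 <= self.flow_level < len(self.unet_channels)):
            raise ValueError("flow_level must be in [0, len(unet_channels))")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class UNet3D:
    """Encoder-decoder displacement-field predictor with manual backprop."""

    def __init__(self, config: RegistrationConfig):
        config.validate()
        self.config = config
        ch = list(config.unet_channels)
        self.levels = len(ch)
        rng = np.random.default_rng([config.seed, 17])
        cin = 2
        self.enc_convs, self.enc_acts, self.pools = [], [], []
        for c in ch:
            self.enc_convs.append(Conv3d(cin, c, rng))
            self.enc_acts.append(LeakyReLU())
            self.pools.append(AvgPool2())
            cin = c
        self.bott_conv = Conv3d(ch[-1], ch[-1], rng)
        self.bott_act = LeakyReLU()
        self.flow_level = config.flow_level
        self.dec_levels = self.levels - self.flow_level
        self.ups, self.dec_convs, self.dec_acts = [], [], []
        up_ch = ch[-1]
        for i in reversed(range(self.flow_level, self.levels)):
            self.ups.append(UpsampleNearest2())
            self.dec_convs.append(Conv3d(up_ch + ch[i], ch[i], rng))
            self.dec_acts.append(LeakyReLU())
            up_ch = ch[i]
        self.refine_conv = Conv3d(up_ch, up_ch, rng)
        self.refine_act = LeakyReLU()
        self.flow_conv = Conv3d(up_ch, 3, rng, zero_init=True)
        self.flow_ups = [UpsampleNearest2() for _ in range(self.flow_level)]
        log.info("UNet3D: channels=%s, flow_level=%d, %d parameters",
                 ch, self.flow_level, self.n_parameters())

    # -- parameter plumbing --

    def _layers_with_params(self):
        return (
            self.enc_convs + [self.bott_conv] + self.dec_convs
            + [self.refine_conv, self.flow_conv]
        )

    def parameters(self):
        params = []
        for layer in self._layers_with_params():
            params.extend(layer.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    # -- forward / backward --

    def check_shape(self, shape) -> None:
        div = 2**self.levels
        if any(s % div for s in shape):
            raise ShapeError(
                f"crop shape {tuple(shape)} not divisible by 2^{self.levels}; "
                f"pad to a multiple of {div}"
            )

    def forward(self, source: np.ndarray, target: np.ndarray) -> np.ndarray:
        """Predict the displacement field warping ``source`` toward ``target``."""
        if source.shape != target.shape:
            raise ShapeError("source and target crops must share a shape")
        self.check_shape(source.shape)
        h = np.stack([source, target], axis=-1).astype(np.float32)
        skips = []
        for conv, act, pool in zip(self.enc_convs, self.enc_acts, self.pools):
            h = act.forward(conv.forward(h))
            skips.append(h)
            h = pool.forward(h)
        h = self.bott_act.forward(self.bott_conv.forward(h))
        self._skip_channels = []
        for k, i in enumerate(reversed(range(self.flow_level, self.levels))):
            h = self.ups[k].forward(h)
            self._skip_channels.append((h.shape[-1], skips[i].shape[-1]))
            h = np.concatenate([h, skips[i]], axis=-1)
            h = self.dec_acts[k].forward(self.dec_convs[k].forward(h))
        h = self.refine_act.forward(self.refine_conv.forward(h))
        flow = self.flow_conv.forward(h)
        for up in self.flow_ups:
            flow = up.forward(flow)
        return flow

    def backward(self, dflow: np.ndarray) -> None:
        for up in reversed(self.flow_ups):
            dflow = up.backward(dflow)
        dh = self.flow_conv.backward(np.ascontiguousarray(dflow, dtype=np.float32))
        dh = self.refine_conv.backward(self.refine_act.backward(dh))
        dskips = [None] * self.levels
        for k in reversed(range(self.dec_levels)):
            i = self.levels - 1 - k
            dh = self.dec_convs[k].backward(self.dec_acts[k].backward(dh))
            up_c, skip_c = self._skip_channels[k]
            dskip = dh[..., up_c:]
            dh = self.ups[k].backward(np.ascontiguousarray(dh[..., :up_c]))
            dskips[i] = dskip
        dh = self.bott_conv.backward(self.bott_act.backward(dh))
        for i in reversed(range(self.levels)):
            dh = self.pools[i].backward(dh)
            if dskips[i] is not None:
                dh = dh + dskips[i]
            dh = self.enc_convs[i].backward(self.enc_acts[i].backward(dh))
        # gradient w.r.t. the input crops is not needed

    # -- checkpointing --

    def state_arrays(self) -> dict:
        return {f"p{i}": p.value for i, p in enumerate(self.parameters())}

    def save(self, path) -> None:
        arrays = self.state_arrays()
        arrays["_config"] = np.frombuffer(
            json.dumps(dataclasses.asdict(self.config)).encode(), dtype=np.uint8
        )
        arrays["_config_hash"] = np.frombuffer(self.config.hash().encode(), dtype=np.uint8)
        np.savez_compressed(str(path), **arrays)

    @classmethod
    def load(cls, path) -> "UNet3D":
        with np.load(str(path)) as data:
            cfg_json = bytes(data["_config"]).decode()
            config = RegistrationConfig(**{
                k: tuple(v) if k == "unet_channels" else v
                for k, v in json.loads(cfg_json).items()
            })
            model = cls(config)
            for i, p in enumerate(model.parameters()):
                p.value[...] = data[f"p{i}"]
        return model


def build_unet(config: RegistrationConfig) -> UNet3D:
    """Construct the registration U-Net for a given configuration."""
    return UNet3D(config)
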