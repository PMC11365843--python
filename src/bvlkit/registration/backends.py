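"""Registration backends: one contract, several implementations.

A backend maps ``(source_crop, target_crop)`` to the displacement field that
pull-warps source toward target.  Implementations:

* :class:`UNetBackend` -- the trained network (the production path);
* :class:`InstanceOptBackend` -- per-pair gradient descent on the field
  itself under the same loss (no training; slower per pair);
* :class:`OracleBackend` -- returns the phantom's exact fields, keyed by
  which crop is the source; makes everything downstream of registration
  testable independently of training quality;
* :class:`FixedFieldsBackend` -- fields loaded from files.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
from scipy.ndimage import gaussian_filter

from .fields import DeformationField
from .losses import registration_loss_grad
from .unet import RegistrationConfig, UNet3D


class RegistrationBackend(Protocol):
    def predict(self, source: np.ndarray, target: np.ndarray) -> DeformationField: ...


def predict_field(backend: RegistrationBackend, source, target) -> DeformationField:
    """Displacement field warping ``source`` toward ``target`` (pull convention)."""
    src = np.asarray(source.data if hasattr(source, "data") else source, np.float32)
    tgt = np.asarray(target.data if hasattr(target, "data") else target, np.float32)
    if src.shape != tgt.shape:
        raise ValueError(f"crop shape mismatch: {src.shape} vs {tgt.shape}")
    field = backend.predict(src, tgt)
    if field.shape != src.shape:
        raise ValueError("backend returned a field on the wrong grid")
    return field


class UNetBackend:
    """Trained-network backend.

    With ``symmetric=True`` (default) the prediction is antisymmetrized over
    the input order, ``u = (f(src, tgt) - f(tgt, src)) / 2``: an
    inverse-consistency construction that guarantees an exactly zero field
    for identical inputs and cancels any order-independent drift the network
    may have acquired, at the cost of a second forward pass.
    """

    def __init__(self, model: UNet3D, symmetric: bool = True):
        self.model = model
        self.symmetric = symmetric

    def predict(self, source: np.ndarray, target: np.ndarray) -> DeformationField:
        flow = self.model.forward(source, target)
        if self.symmetric:
            flow = 0.5 * (flow - self.model.forward(target, source))
        return DeformationField(flow, direction_tag="source->target")


class OracleBackend:
    """Exact phantom fields behind the backend contract.

    Decides direction by matching the source crop against the stored BL/FU
    crops (after the same normalization the pipeline applies).
    """

    def __init__(self, bl_crop: np.ndarray, fu_crop: np.ndarray,
                 field_fw: DeformationField, field_bw: DeformationField):
        self.bl = np.asarray(bl_crop, np.float32)
        self.fu = np.asarray(fu_crop, np.float32)
        self.field_fw = field_fw
        self.field_bw = field_bw

    def predict(self, source: np.ndarray, target: np.ndarray) -> DeformationField:
        if np.array_equal(source, self.bl):
            return self.field_fw
        if np.array_equal(source, self.fu):
            return self.field_bw
        raise ValueError("OracleBackend: source crop matches neither stored crop")


class FixedFieldsBackend(OracleBackend):
    """Fields read from displacement NIfTIs (same matching rule as the oracle)."""

    @classmethod
    def from_paths(cls, bl_crop, fu_crop, path_fw, path_bw) -> "FixedFieldsBackend":
        return cls(
            np.asarray(bl_crop, np.float32), np.asarray(fu_crop, np.float32),
            DeformationField.load(path_fw, "BL->FU"),
            DeformationField.load(path_bw, "FU->BL"),
        )


class InstanceOptBackend:
    """Per-pair optimization of the displacement field under the same loss.

    Adam on the raw field with an optional Gaussian pre-smoothing of the
    gradient (a cheap stand-in for a coarse-to-fine schedule).  Deterministic:
    no randomness is involved.
    """

    def __init__(self, config: RegistrationConfig | None = None, iters: int = 120,
                 lr: float = 0.1, grad_sigma: float = 1.0):
        self.config = config or RegistrationConfig()
        self.iters = iters
        self.lr = lr
        self.grad_sigma = grad_sigma

    def predict(self, source: np.ndarray, target: np.ndarray) -> DeformationField:
        flow = np.zeros(source.shape + (3,), dtype=np.float32)
        m = np.zeros_like(flow)
        v = np.zeros_like(flow)
        b1, b2, eps = 0.9, 0.999, 1e-8
        for t in range(1, self.iters + 1):
            _, g = registration_loss_grad(
                source, target, flow,
                smoothness_weight=self.config.smoothness_weight,
                win=self.config.ncc_window,
                magnitude_weight=self.config.magnitude_weight,
            )
            if self.grad_sigma > 0:
                for c in range(3):
                    g[..., c] = gaussian_filter(g[..., c], self.grad_sigma)
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            flow -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return DeformationField(flow, direction_tag="source->target")
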