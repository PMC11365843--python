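"""Unsupervised registration loss: local NCC similarity + field smoothness.

``loss = -localNCC(warped_source, target) + lambda * mean |forward-diff grad u|^2``

Local NCC uses a cubic window (default edge 9).  Per window the squared
correlation is ``cc = (cross^2 + eps) / (varI * varJ + eps)`` with
``eps = 1e-5``: the epsilon regularizes zero-variance windows (never NaN) and
makes a perfect match score exactly 1 everywhere, so the similarity term of
an identical pair under a zero field is exactly -1.  By Cauchy-Schwarz
``cc <= 1``.

Both terms come with hand-derived gradients; the spatial transformer
(trilinear pull-warp with border clamping) provides the gradient of the
warped image with respect to the displacement field.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

NCC_EPS = 1e-5


def _boxmean(x: np.ndarray, win: int) -> np.ndarray:
    return uniform_filter(x, size=win, mode="constant", cval=0.0)


def local_ncc(warped: np.ndarray, target: np.ndarray, win: int = 9, eps: float = NCC_EPS) -> float:
    """Mean windowed squared normalized cross-correlation (in [0, 1])."""
    if win % 2 == 0:
        raise ValueError("ncc window must be odd")
    i = target.astype(np.float32)
    j = warped.astype(np.float32)
    mi, mj = _boxmean(i, win), _boxmean(j, win)
    cross = _boxmean(i * j, win) - mi * mj
    vi = np.maximum(_boxmean(i * i, win) - mi * mi, 0.0)
    vj = np.maximum(_boxmean(j * j, win) - mj * mj, 0.0)
    cc = (cross * cross + eps) / (vi * vj + eps)
    return float(cc.mean())


def ncc_loss_grad(warped: np.ndarray, target: np.ndarray, win: int = 9, eps: float = NCC_EPS):
    """Similarity loss ``-mean(cc)`` and its gradient w.r.t. ``warped``."""
    i = target.astype(np.float32)
    j = warped.astype(np.float32)
    mi, mj = _boxmean(i, win), _boxmean(j, win)
    cross = _boxmean(i * j, win) - mi * mj
    vi = np.maximum(_boxmean(i * i, win) - mi * mi, 0.0)
    vj = np.maximum(_boxmean(j * j, win) - mj * mj, 0.0)
    denom = vi * vj + eps
    cc = (cross * cross + eps) / denom
    loss = -float(cc.mean())

    n_vox = j.size
    a = 2.0 * cross / denom                    # dcc/dcross
    b = (cross * cross + eps) * vi / denom**2  # -dcc/dvj
    # window sums via the (self-adjoint) box-mean operator
    grad = -(i * _boxmean(a, win) - _boxmean(a * mi, win)
             - 2.0 * j * _boxmean(b, win) + 2.0 * _boxmean(b * mj, win)) / n_vox
    return loss, grad.astype(np.float32)


def smoothness_loss_grad(flow: np.ndarray, weight: float = 1.0):
    """Mean squared forward-difference gradient of the field, with gradient.

    Constant fields are perfectly smooth (zero penalty).
    """
    loss = 0.0
    grad = np.zeros_like(flow)
    n = flow[..., 0].size * 3  # normalizer: components x voxels (per axis)
    for ax in range(3):
        d = np.diff(flow, axis=ax)
        loss += float((d.astype(np.float64) ** 2).sum()) / n
        g = 2.0 * d / n
        sl_lo = [slice(None)] * 4
        sl_hi = [slice(None)] * 4
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        grad[tuple(sl_hi)] += g
        grad[tuple(sl_lo)] -= g
    return weight * loss / 3.0, (weight / 3.0) * grad


def warp_with_grad(source: np.ndarray, flow: np.ndarray):
    """Trilinear pull-warp with the ingredients for the flow gradient.

    Returns ``(warped, backward)`` where ``backward(dwarped)`` gives the loss
    gradient w.r.t. ``flow``.  Sampling coordinates are clamped to the grid
    (border replication) so the gradient is well defined everywhere.
    """
    shape = source.shape
    grids = np.meshgrid(*[np.arange(n, dtype=np.float32) for n in shape], indexing="ij")
    coords = [g + flow[..., ax] for ax, g in enumerate(grids)]
    w1, idx0, idx1, active = [], [], [], []
    for ax, c in enumerate(coords):
        # clamped samples replicate the border; their derivative w.r.t. the
        # coordinate is zero, so the gradient is masked there
        active.append(((c > 0.0) & (c < shape[ax] - 1.0)).astype(np.float32))
        c = np.clip(c, 0.0, shape[ax] - 1.0)
        i0 = np.floor(c).astype(np.int32)
        i0 = np.minimum(i0, shape[ax] - 2)
        frac = c - i0
        idx0.append(i0)
        idx1.append(i0 + 1)
        w1.append(frac.astype(np.float32))
    src = source.astype(np.float32)

    corners = {}
    for bz in (0, 1):
        for by in (0, 1):
            for bx in (0, 1):
                iz = idx1[0] if bz else idx0[0]
                iy = idx1[1] if by else idx0[1]
                ix = idx1[2] if bx else idx0[2]
                corners[(bz, by, bx)] = src[iz, iy, ix]

    wz, wy, wx = w1
    warped = np.zeros(shape, dtype=np.float32)
    for (bz, by, bx), val in corners.items():
        weight = ((wz if bz else 1 - wz) * (wy if by else 1 - wy) * (wx if bx else 1 - wx))
        warped += weight * val

    def backward(dwarped: np.ndarray) -> np.ndarray:
        dflow = np.zeros(shape + (3,), dtype=np.float32)
        # d warped / d c_z = sum over corners of (+-1) * wy-part * wx-part * val
        dz = np.zeros(shape, dtype=np.float32)
        dy = np.zeros(shape, dtype=np.float32)
        dx = np.zeros(shape, dtype=np.float32)
        for (bz, by, bx), val in corners.items():
            pz = (1.0 if bz else -1.0)
            py = (1.0 if by else -1.0)
            px = (1.0 if bx else -1.0)
            fz = wz if bz else 1 - wz
            fy = wy if by else 1 - wy
            fx = wx if bx else 1 - wx
            dz += pz * fy * fx * val
            dy += fz * py * fx * val
            dx += fz * fy * px * val
        dflow[..., 0] = dwarped * dz * active[0]
        dflow[..., 1] = dwarped * dy * active[1]
        dflow[..., 2] = dwarped * dx * active[2]
        return dflow

    return warped, backward


def magnitude_loss_grad(flow: np.ndarray, weight: float):
    """Weak zero-displacement prior: ``weight * mean(u^2)`` over components.

    Pins down the displacement in regions where the similarity term is flat
    (uniform tissue, background) and the smoothness term is blind (constant
    drift has zero gradient); negligible for genuine deformations when the
    weight is small.
    """
    if weight == 0:
        return 0.0, 0.0
    n = flow.size
    loss = weight * float((flow.astype(np.float64) ** 2).sum()) / n
    return loss, (2.0 * weight / n) * flow


def registration_loss(source: np.ndarray, target: np.ndarray, flow: np.ndarray,
                      smoothness_weight: float = 1.0, win: int = 9,
                      magnitude_weight: float = 0.0) -> float:
    """The scalar training objective for a (source, target, flow) triple."""
    warped, _ = warp_with_grad(source, flow)
    loss_sim = -local_ncc(warped, target, win=win)
    loss_smooth, _ = smoothness_loss_grad(flow, smoothness_weight)
    loss_mag, _ = magnitude_loss_grad(flow, magnitude_weight)
    return loss_sim + loss_smooth + loss_mag


def registration_loss_grad(source: np.ndarray, target: np.ndarray, flow: np.ndarray,
                           smoothness_weight: float = 1.0, win: int = 9,
                           magnitude_weight: float = 0.0):
    """Loss and gradient w.r.t. the flow (used by training and instance optimization)."""
    warped, backward = warp_with_grad(source, flow)
    loss_sim, dwarped = ncc_loss_grad(warped, target, win=win)
    loss_smooth, dflow_smooth = smoothness_loss_grad(flow, smoothness_weight)
    loss_mag, dflow_mag = magnitude_loss_grad(flow, magnitude_weight)
    dflow = backward(dwarped) + dflow_smooth + dflow_mag
    return loss_sim + loss_smooth + loss_mag, dflow
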