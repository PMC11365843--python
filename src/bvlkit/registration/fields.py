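"""Dense displacement fields and warping.

Conventions (recorded once, used everywhere):

* Displacements are stored **in voxels** on the same grid as the crops,
  channels-last: ``disp.shape == crop_shape + (3,)``.
* :func:`warp` is a **pull** (backward) warp: output voxel ``x`` samples the
  input at ``x + u(x)`` with trilinear interpolation and zero padding.  This
  matches the spatial-transformer convention of unsupervised registration
  networks, so a field predicted for (source, target) warps *source* toward
  *target* and fractional boundary values of warped binary masks are
  preserved ("soft" masks).
* A *forward* (Lagrangian) field for the same map ``phi`` carries
  ``u_fwd(x) = phi(x) - x``; Jacobian-determinant integration expects this
  representation.  Analytic constructors below can emit either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from ..volume import Volume3D


@dataclass
class DeformationField:
    """Per-voxel 3-vector displacement field, in voxels, channels-last."""

    disp: np.ndarray
    direction_tag: str = ""

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValueError(f"expected (D, H, W, 3) displacements, got {self.disp.shape}")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[:3]  # type: ignore[return-value]

    @classmethod
    def zero(cls, shape, direction_tag: str = "") -> "DeformationField":
        return cls(np.zeros(tuple(shape) + (3,), dtype=np.float32), direction_tag)

    def to_nifti_volume(self, affine=None) -> "np.ndarray":
        """4D array view suitable for writing as a displacement NIfTI."""
        return self.disp

    def save(self, path, affine=None) -> None:
        import nibabel as nib

        aff = np.eye(4) if affine is None else np.asarray(affine)
        img = nib.Nifti1Image(self.disp.astype(np.float32), aff)
        img.header["descrip"] = b"displacement field, voxel units, pull convention"
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, direction_tag: str = "") -> "DeformationField":
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        return cls(np.asarray(data, dtype=np.float32), direction_tag)


def _sample_grid(shape) -> np.ndarray:
    """Voxel-index grid, shape (D, H, W, 3)."""
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def warp(volume, field: DeformationField, order: int = 1) -> np.ndarray:
    """Pull-warp a volume (or mask) through ``field``.

    Output voxel ``x`` takes the trilinear sample of the input at
    ``x + field(x)``; samples outside the grid are zero.  Binary masks come
    back fractional at boundaries -- deliberately not re-thresholded.
    """
    data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume)
    if data.shape != field.shape:
        raise ValueError(f"grid mismatch: volume {data.shape} vs field {field.shape}")
    coords = _sample_grid(data.shape) + field.disp
    out = map_coordinates(
        data.astype(np.float64, copy=False),
        np.moveaxis(coords, -1, 0),
        order=order,
        mode="constant",
        cval=0.0,
    )
    return out.astype(data.dtype if np.issubdtype(data.dtype, np.floating) else np.float64)


def warp_volume(volume: Volume3D, field: DeformationField, order: int = 1) -> Volume3D:
    return Volume3D(warp(volume, field, order=order), volume.affine)


# --- analytic fields ---------------------------------------------------------


def uniform_scale_field(shape, scale: float, kind: str = "pull", center=None) -> DeformationField:
    """Field of the global scaling map ``phi(x) = c + scale * (x - c)``.

    ``kind='forward'`` gives the Lagrangian displacement ``(scale-1)(x-c)``
    (``det(I + grad u) = scale**3`` exactly); ``kind='pull'`` gives the
    sampling field ``(1/scale - 1)(x-c)`` that warps an image onto its scaled
    version, so a warped mask's soft volume changes by ``scale**3``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    c = (np.asarray(shape, dtype=float) - 1) / 2 if center is None else np.asarray(center, float)
    grid = _sample_grid(shape) - c
    if kind == "forward":
        coeff = scale - 1.0
    elif kind == "pull":
        coeff = 1.0 / scale - 1.0
    else:
        raise ValueError("kind must be 'forward' or 'pull'")
    return DeformationField((coeff * grid).astype(np.float32), direction_tag=f"scale:{kind}")


def radial_profile_amplitude(kappa: float, bvl_percent: float) -> float:
    """Amplitude ``A`` of the radial atrophy profile hitting a target volume change.

    The map acts on the TIV-normalized radius ``r = |y|`` as
    ``g(r) = r + A * r * (1 - r**2)**2`` for ``r <= 1`` (identity outside).
    It fixes the TIV surface (``g(1) = 1``) and moves the ventricle surface
    at ``r = kappa`` so that the parenchyma shell volume changes by exactly
    ``bvl_percent`` percent:  ``(1 - g(kappa)**3) / (1 - kappa**3) = 1 + t``.
    """
    if not (0 < kappa < 1):
        raise ValueError("kappa (ventricle/TIV radius ratio) must be in (0, 1)")
    t = bvl_percent / 100.0
    gk3 = 1.0 - (1.0 + t) * (1.0 - kappa**3)
    if gk3 <= 0:
        raise ValueError(
            f"true_bvl_percent={bvl_percent} unreachable by the radial mode with kappa={kappa}"
        )
    gk = gk3 ** (1.0 / 3.0)
    amp = (gk - kappa) / (kappa * (1.0 - kappa**2) ** 2)
    # monotonicity of g on [0, 1]: folding would invalidate the closed form
    r = np.linspace(0.0, 1.0, 257)
    gprime = 1.0 + amp * (1.0 - r**2) * (1.0 - 5.0 * r**2)
    if np.any(gprime <= 0):
        raise ValueError(
            f"true_bvl_percent={bvl_percent} folds the radial field (g' <= 0); "
            "reduce |BVL| or enlarge the ventricle"
        )
    return float(amp)


def _radial_g(r: np.ndarray, amp: float) -> np.ndarray:
    return r + amp * r * (1.0 - r**2) ** 2


def _radial_g_inverse(r_target: np.ndarray, amp: float, iters: int = 12) -> np.ndarray:
    """Invert ``g`` on [0, 1] by vectorized Newton iteration (g is monotone)."""
    r = np.clip(r_target, 0.0, 1.0).copy()
    for _ in range(iters):
        gp = 1.0 + amp * (1.0 - r**2) * (1.0 - 5.0 * r**2)
        r = r - (_radial_g(r, amp) - r_target) / gp
        np.clip(r, 0.0, 1.0, out=r)
    return r


def radial_atrophy_field(
    shape,
    tiv_radii_vox,
    kappa: float,
    bvl_percent: float,
    kind: str = "pull",
    center=None,
) -> DeformationField:
    """Analytic radial atrophy field on a voxel grid (identity outside the TIV).

    ``tiv_radii_vox`` are the TIV ellipsoid semi-axes in voxels; the map is
    radial in the TIV-normalized coordinate, so its parenchyma volume change
    has the closed form used by :func:`radial_profile_amplitude`.
    """
    amp = radial_profile_amplitude(kappa, bvl_percent)
    a = np.asarray(tiv_radii_vox, dtype=float)
    c = (np.asarray(shape, dtype=float) - 1) / 2 if center is None else np.asarray(center, float)
    y = (_sample_grid(shape) - c) / a
    r = np.linalg.norm(y, axis=-1)
    inside = (r < 1.0) & (r > 0)
    disp = np.zeros(tuple(shape) + (3,), dtype=np.float64)
    rin = r[inside]
    if kind == "forward":
        factor = _radial_g(rin, amp) / rin - 1.0
    elif kind == "pull":
        factor = _radial_g_inverse(rin, amp) / rin - 1.0
    else:
        raise ValueError("kind must be 'forward' or 'pull'")
    disp[inside] = y[inside] * factor[:, None] * a
    return DeformationField(disp.astype(np.float32), direction_tag=f"radial:{kind}")
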