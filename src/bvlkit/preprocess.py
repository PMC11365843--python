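"""Halfway-space preprocessing: reslice, head crop, rigid halfway registration.

A baseline/follow-up pair enters registration as two crops on an identical
grid in a *halfway* frame: the rigid motion between the scans is estimated
once and each image is resampled through half of it (exact matrix square
root), so both images undergo exactly one interpolation and neither is
privileged -- the construction that removes single-interpolation asymmetry
bias from longitudinal change estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .volume import MetadataError, RigidTransform, Volume3D


class SegmentationFailureError(RuntimeError):
    pass


class RegistrationError(RuntimeError):
    pass


DEFAULT_CROP_SHAPE = (176, 208, 208)
"""Matrix size covering skull and brainstem at 1 mm (configurable)."""


@dataclass
class CropPair:
    """A BL/FU pair brought onto one grid in the halfway frame."""

    bl_crop: Volume3D
    fu_crop: Volume3D
    half_bl: RigidTransform
    """World-space transform applied to BL coordinates into the halfway frame."""
    half_fu: RigidTransform
    crop_origin: np.ndarray | None = None
    crop_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.bl_crop.shape != self.fu_crop.shape:
            raise ValueError("halfway crops must share a shape")


# --- reslicing ---------------------------------------------------------------


def reslice_isotropic(vol: Volume3D, target_mm: float = 1.0) -> Volume3D:
    """Reslice to isotropic voxels in canonical (RAS, transversal) orientation.

    Trilinear interpolation on a grid covering the original field of view;
    world coordinates are preserved through the output affine.  A volume that
    is already isotropic at ``target_mm`` and canonically oriented is
    returned unchanged (no interpolation).
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    import nibabel as nib

    img = vol.to_nifti()
    canonical = nib.as_closest_canonical(img)
    can_vol = Volume3D.from_nifti(canonical)
    if np.allclose(can_vol.voxel_mm, target_mm, atol=1e-6) and np.allclose(
        can_vol.affine[:3, :3], np.diag([target_mm] * 3), atol=1e-6
    ):
        return can_vol
    from nibabel.processing import resample_to_output

    out = resample_to_output(canonical, voxel_sizes=(target_mm,) * 3, order=1, cval=0.0)
    res = Volume3D.from_nifti(out)
    return Volume3D(res.data.astype(np.float32), res.affine)


# --- head crop ---------------------------------------------------------------


def head_crop_box(vol: Volume3D, shape=DEFAULT_CROP_SHAPE, threshold_frac: float = 0.05) -> np.ndarray:
    """Start indices of the head crop box (see :func:`crop_head`)."""
    data = vol.data
    shape = tuple(int(s) for s in shape)
    if shape == data.shape:
        return np.zeros(3, dtype=int)  # full-FOV request: identity crop
    ref = np.percentile(data, 99.9)
    fg = data > threshold_frac * ref
    if not fg.any() or ref <= 0:
        raise SegmentationFailureError("no foreground voxels above threshold")
    idx = np.nonzero(fg)
    lo = np.array([a.min() for a in idx])
    hi = np.array([a.max() for a in idx])
    start = np.zeros(3, dtype=int)
    for ax in (0, 1):
        center = (lo[ax] + hi[ax]) // 2
        start[ax] = center - shape[ax] // 2
    start[2] = hi[2] + 1 - shape[2]  # top-aligned on the superior axis
    return start


def apply_crop(vol: Volume3D, start: np.ndarray, shape) -> Volume3D:
    """Extract a fixed-shape box at ``start`` (zero-padded outside the FOV)."""
    data = vol.data
    shape = tuple(int(s) for s in shape)
    start = np.asarray(start, dtype=int)
    out = np.zeros(shape, dtype=data.dtype)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + np.array(shape), data.shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.any(src_hi <= src_lo):
        raise SegmentationFailureError("crop box does not intersect the volume")
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = data[
        src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
    ]
    new_affine = vol.affine.copy()
    new_affine[:3, 3] = vol.affine[:3, 3] + vol.affine[:3, :3] @ start
    return Volume3D(out, new_affine)


def crop_head(vol: Volume3D, shape=DEFAULT_CROP_SHAPE, threshold_frac: float = 0.05) -> Volume3D:
    """Crop a fixed-shape box positioned by the head bounding box.

    Foreground is intensity above ``threshold_frac`` of the robust maximum
    (99.9th percentile).  The box is centered on the foreground in the first
    two axes and top-aligned to the superior foreground extent on the third
    (covering skull down toward the foramen magnum); zero-padded wherever the
    field of view is smaller than the requested shape.  Use
    :func:`head_crop_box` + :func:`apply_crop` to crop masks with the same
    box as their image.
    """
    return apply_crop(vol, head_crop_box(vol, shape, threshold_frac), shape)


# --- rigid halfway registration ----------------------------------------------


def _to_sitk(vol: Volume3D) -> sitk.Image:
    # Volume3D grids here are axis-aligned (post-reslice); hand SimpleITK the
    # spacing only and keep world bookkeeping in our affines.
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.astype(np.float32)).transpose(2, 1, 0))
    img.SetSpacing(tuple(float(s) for s in vol.voxel_mm))
    return img


def estimate_rigid(bl: Volume3D, fu: Volume3D, metric: str = "ncc",
                   pyramid=(4, 2, 1)) -> RigidTransform:
    """Estimate the rigid transform mapping FU coordinates onto BL.

    Multi-resolution intensity-driven optimization (SimpleITK registration
    framework, Euler parameterization, gradient-descent with physical-shift
    scale estimation).  Returns the world-space motion ``T`` with
    ``BL(x) ~ FU(T(x))`` ... i.e. resampling FU through ``T`` aligns it to BL.
    """
    fixed = _to_sitk(bl)
    moving = _to_sitk(fu)
    reg = sitk.ImageRegistrationMethod()
    if metric == "mi":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    else:
        reg.SetMetricAsCorrelation()
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.25, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(pyramid))
    reg.SetSmoothingSigmasPerLevel([float(max(f - 1, 0)) for f in pyramid])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    init = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=False)
    try:
        final = reg.Execute(fixed, moving)
    except RuntimeError as exc:  # pragma: no cover - optimizer blow-up
        raise RegistrationError(f"rigid registration failed: {exc}") from exc
    final = sitk.Euler3DTransform(sitk.CompositeTransform(final).GetNthTransform(0))
    rot = np.asarray(final.GetMatrix(), dtype=float).reshape(3, 3)
    center = np.asarray(final.GetCenter(), dtype=float)
    trans = np.asarray(final.GetTranslation(), dtype=float)
    # sitk maps fixed physical points to moving: y = R (x - c) + c + t
    t_world = center + trans - rot @ center
    return RigidTransform(rotation=rot, translation=t_world)


def _resample_through(vol: Volume3D, world_map: RigidTransform) -> Volume3D:
    """Resample so that output voxel x holds vol sampled at world_map(x) (one interpolation)."""
    inv_aff = np.linalg.inv(vol.affine)
    shape = vol.shape
    axes = [np.arange(n, dtype=float) for n in shape]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij", sparse=False)
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = vox @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    src_world = world_map.apply(world)
    src_vox = src_world @ inv_aff[:3, :3].T + inv_aff[:3, 3]
    out = map_coordinates(
        vol.data.astype(np.float64), src_vox.T.reshape(3, *shape),
        order=1, mode="constant", cval=0.0,
    )
    return Volume3D(out.astype(np.float32), vol.affine)


def rigid_register_halfway(bl: Volume3D, fu: Volume3D, metric: str = "ncc") -> CropPair:
    """Rigidly align BL and FU in halfway space (one interpolation each).

    The estimated motion ``T`` (FU -> BL sense, see :func:`estimate_rigid`)
    is split into its exact square root ``H``; BL is resampled through
    ``H^-1``... more precisely output-voxel sampling maps are chosen so the
    two resampled images meet in the frame midway along the motion, and the
    two half-transforms are returned.
    """
    if bl.shape != fu.shape or not np.allclose(bl.voxel_mm, fu.voxel_mm):
        raise ValueError("halfway registration expects same-grid crops")
    t = estimate_rigid(bl, fu, metric=metric)
    half = t.sqrt()  # H with H o H == T
    # sampling maps: BL sampled at H^(1/2)-inverse ... BL(x') with x' = H^-1(x)?
    # Convention: halfway frame h; BL lives at h after applying H^-1 to its
    # coordinates, FU after applying H. Output voxel x pulls BL at H(x)^-1 ...
    bl_half = _resample_through(bl, half.inverse())
    fu_half = _resample_through(fu, half)
    return CropPair(
        bl_crop=bl_half, fu_crop=fu_half,
        half_bl=half.inverse(), half_fu=half,
        crop_shape=bl.shape,
    )


def resample_mask_like(mask: Volume3D, world_map: RigidTransform, threshold: float = 0.5) -> Volume3D:
    """Bring a binary mask through a rigid map (trilinear, re-thresholded)."""
    soft = _resample_through(Volume3D(mask.data.astype(np.float32), mask.affine), world_map)
    return Volume3D((soft.data >= threshold).astype(np.uint8), soft.affine)


def normalize_crop(vol: Volume3D, threshold_frac: float = 0.05) -> Volume3D:
    """Zero-mean/unit-SD normalization inside the foreground box (registration input)."""
    data = vol.data.astype(np.float32)
    ref = np.percentile(data, 99.9)
    fg = data > threshold_frac * max(ref, 1e-12)
    if not fg.any():
        raise SegmentationFailureError("cannot normalize an empty crop")
    mu = float(data[fg].mean())
    sd = float(data[fg].std())
    if sd == 0:
        raise SegmentationFailureError("zero intensity variance in foreground")
    return Volume3D((data - mu) / sd, vol.affine)
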