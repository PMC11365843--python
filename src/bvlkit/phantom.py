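"""Synthetic longitudinal brain phantom with exact volumetric ground truth.

The phantom is deliberately geometric rather than anatomical: four nested
compartments (background, skull shell, CSF, brain parenchyma around a central
ventricle) built from axis-aligned ellipsoids.  Every transformation applied
to make a follow-up scan -- radial atrophy, global "scanner distortion"
scaling, noise -- maps ellipsoids to ellipsoids, so compartment volumes, the
deformation field and the percentage brain volume loss (BVL) are all known in
closed form.  Exact ground truth is what makes the downstream volumetry and
calibration testable without clinical data.

Atrophy modes
-------------
``radial``
    Smooth radial contraction/expansion of the parenchyma shell in
    TIV-normalized coordinates, fixing the TIV surface and moving the
    ventricle surface; the amplitude hitting a requested BVL has a closed
    form (see :func:`bvlkit.registration.fields.radial_profile_amplitude`).
    Requires the ventricle semi-axes to be proportional to the TIV semi-axes.
``uniform-scale``
    Global isotropic scaling of the parenchyma compartment about the grid
    center; the brain surface detaches from the TIV surface, leaving a CSF
    rim.  No image-consistent deformation exists on that rim (CSF is created,
    not advected), so the stored true field interpolates displacement
    linearly across it; parenchyma volume truth is unaffected.

Scanner distortion is modelled as a global affine scale ``s`` about the grid
center applied to the whole follow-up image: it inflates/deflates brain
parenchyma volume (BPV) and total intracranial volume (TIV) by the identical
factor ``s**3``, which is precisely the assumption the TIV-based distortion
correction exploits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registration.fields import (
    DeformationField,
    _radial_g,
    _radial_g_inverse,
    _sample_grid,
    radial_profile_amplitude,
)
from .volume import Volume3D


class PhantomSizingError(ValueError):
    """Grid too small (or compartments not nested) for the requested geometry."""


class AtrophyParameterizationError(ValueError):
    """Requested atrophy not representable by the chosen mode."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic head.

    Radii are semi-axes in mm; the grid is isotropic with edge ``voxel_mm``.
    Intensities are loosely T1-like (dark CSF, bright parenchyma); their
    absolute values are irrelevant downstream because registration operates
    on normalized crops.
    """

    grid_size: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 1.0
    skull_radii_mm: tuple[float, float, float] = (24.0, 28.0, 24.0)
    tiv_radii_mm: tuple[float, float, float] = (20.0, 24.0, 20.0)
    ventricle_radii_mm: tuple[float, float, float] = (5.0, 6.0, 5.0)
    tissue_intensities: tuple[float, float, float, float] = (0.0, 60.0, 25.0, 100.0)
    """(background, skull, CSF, parenchyma) mean intensities."""
    noise_sigma: float = 0.0
    rician: bool = False
    edge_mm: float = 1.5
    """Width of the smooth boundary profile (gives registration its gradients)."""
    seed: int = 0

    def validate(self) -> None:
        names = "xyz"
        skull = np.asarray(self.skull_radii_mm)
        tiv = np.asarray(self.tiv_radii_mm)
        vent = np.asarray(self.ventricle_radii_mm)
        if np.any(skull <= 0) or np.any(tiv <= 0) or np.any(vent < 0):
            raise PhantomSizingError("all radii must be positive (ventricle may be 0)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if np.any(vent >= tiv) or np.any(tiv >= skull):
            raise PhantomSizingError("compartments must nest: ventricle < TIV < skull")
        half_extent = (np.asarray(self.grid_size) - 1) / 2 * self.voxel_mm
        margin = self.edge_mm
        for ax in range(3):
            if skull[ax] + margin > half_extent[ax]:
                raise PhantomSizingError(
                    f"grid too small along axis {names[ax]}: skull semi-axis "
                    f"{skull[ax]} mm + edge {margin} mm exceeds half-extent "
                    f"{half_extent[ax]:.1f} mm"
                )

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_size) - 1) / 2 * self.voxel_mm

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        return aff


@dataclass(frozen=True)
class AtrophySpec:
    """Ground-truth change from baseline to follow-up."""

    true_bvl_percent: float = 0.0
    mode: str = "radial"
    distortion_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if abs(self.true_bvl_percent) >= 10:
            raise AtrophyParameterizationError("|true_bvl_percent| must be < 10")
        if not (0.95 < self.distortion_scale < 1.05):
            raise AtrophyParameterizationError("distortion_scale must be in (0.95, 1.05)")
        if self.mode not in ("radial", "uniform-scale"):
            raise AtrophyParameterizationError(f"unknown atrophy mode {self.mode!r}")


@dataclass
class PhantomTruth:
    """Exact per-pair ground truth (continuum volumes, masks, fields)."""

    bpv_bl_mm3: float
    bpv_fu_mm3: float
    tiv_bl_mm3: float
    tiv_fu_mm3: float
    true_bvl_percent: float
    distortion_scale: float
    true_field: DeformationField
    """Pull field warping the BL crop onto the FU crop (BL->FU direction)."""
    true_field_bw: DeformationField
    """Pull field warping the FU crop onto the BL crop."""
    true_field_forward: DeformationField
    """Lagrangian displacement of the BL->FU map (for Jacobian integration)."""
    masks: dict = field(default_factory=dict)
    """'bl_parenchyma', 'bl_tiv', 'fu_parenchyma', 'fu_tiv' -> Volume3D (uint8)."""


def _ellipsoid_fields(shape, voxel_mm, center_mm, radii_mm):
    """Normalized radius F=|y| and |grad F| on the grid (for soft edges)."""
    coords = _sample_grid(shape) * voxel_mm - center_mm
    y = coords / np.asarray(radii_mm, dtype=float)
    f = np.linalg.norm(y, axis=-1)
    gradnorm = np.linalg.norm(y / np.asarray(radii_mm, dtype=float), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gradnorm = np.where(f > 1e-9, gradnorm / np.maximum(f, 1e-9), 1.0 / np.min(radii_mm))
    return f, gradnorm


def ellipsoid_soft(shape, voxel_mm, center_mm, radii_mm, edge_mm) -> np.ndarray:
    """Anti-aliased indicator of an ellipsoid (smoothstep over ~edge_mm)."""
    f, gradnorm = _ellipsoid_fields(shape, voxel_mm, center_mm, radii_mm)
    dist = (f - 1.0) / np.maximum(gradnorm, 1e-9)  # approx. signed distance, mm
    t = np.clip(0.5 - dist / edge_mm, 0.0, 1.0)
    return (t * t * (3.0 - 2.0 * t)).astype(np.float32)


def ellipsoid_mask(shape, voxel_mm, center_mm, radii_mm) -> np.ndarray:
    f, _ = _ellipsoid_fields(shape, voxel_mm, center_mm, radii_mm)
    return (f <= 1.0).astype(np.uint8)


def _ellipsoid_volume(radii_mm) -> float:
    return float(4.0 / 3.0 * np.pi * np.prod(np.asarray(radii_mm, dtype=float)))


def _render(spec: PhantomSpec, skull, tiv, brain, vent) -> np.ndarray:
    """Compose compartment intensities from nested soft ellipsoid indicators."""
    bg_i, skull_i, csf_i, par_i = spec.tissue_intensities
    args = (spec.grid_size, spec.voxel_mm, spec.center_mm)
    s_skull = ellipsoid_soft(*args, skull, spec.edge_mm)
    s_tiv = ellipsoid_soft(*args, tiv, spec.edge_mm)
    s_brain = ellipsoid_soft(*args, brain, spec.edge_mm)
    img = bg_i + (skull_i - bg_i) * s_skull + (csf_i - skull_i) * s_tiv + (par_i - csf_i) * s_brain
    if np.all(np.asarray(vent) > 0):
        s_vent = ellipsoid_soft(*args, vent, spec.edge_mm)
        img = img + (csf_i - par_i) * s_vent
    return img.astype(np.float32)


def _add_noise(img: np.ndarray, sigma: float, rician: bool, rng: np.random.Generator):
    if sigma <= 0:
        return img
    if rician:
        re = img + rng.normal(0.0, sigma, img.shape)
        im = rng.normal(0.0, sigma, img.shape)
        return np.hypot(re, im).astype(np.float32)
    return (img + rng.normal(0.0, sigma, img.shape)).astype(np.float32)


def make_baseline(spec: PhantomSpec):
    """Render the baseline volume and its exact parenchyma / TIV masks.

    Returns ``(volume, parenchyma_mask, tiv_mask)`` as :class:`Volume3D`
    (float32 intensities, uint8 masks).  Deterministic given ``spec.seed``.
    """
    spec.validate()
    img = _render(spec, spec.skull_radii_mm, spec.tiv_radii_mm, spec.tiv_radii_mm,
                  spec.ventricle_radii_mm)
    rng = np.random.default_rng([spec.seed, 0])
    img = _add_noise(img, spec.noise_sigma, spec.rician, rng)
    args = (spec.grid_size, spec.voxel_mm, spec.center_mm)
    tiv_mask = ellipsoid_mask(*args, spec.tiv_radii_mm)
    if np.all(np.asarray(spec.ventricle_radii_mm) > 0):
        vent_mask = ellipsoid_mask(*args, spec.ventricle_radii_mm)
    else:
        vent_mask = np.zeros(spec.grid_size, dtype=np.uint8)
    par_mask = (tiv_mask & ~vent_mask.astype(bool)).astype(np.uint8)
    aff = spec.affine
    return (
        Volume3D(img, aff),
        Volume3D(par_mask, aff),
        Volume3D(tiv_mask, aff),
    )


def _kappa(spec: PhantomSpec) -> float:
    """Ventricle/TIV radius ratio; radial mode requires proportional axes."""
    ratios = np.asarray(spec.ventricle_radii_mm) / np.asarray(spec.tiv_radii_mm)
    if np.ptp(ratios) > 1e-6:
        raise AtrophyParameterizationError(
            "radial atrophy requires ventricle_radii proportional to tiv_radii "
            f"(got ratios {ratios})"
        )
    return float(ratios[0])


def _true_fields(spec: PhantomSpec, atrophy: AtrophySpec):
    """Exact pull fields (fw: BL->FU, bw: FU->BL) and the forward field, in voxels."""
    shape = spec.grid_size
    c_vox = (np.asarray(shape, dtype=float) - 1) / 2
    a_vox = np.asarray(spec.tiv_radii_mm) / spec.voxel_mm
    s = atrophy.distortion_scale
    if atrophy.true_bvl_percent == 0 and s == 1:
        zero = DeformationField.zero(shape)
        return (
            DeformationField(zero.disp.copy(), "BL->FU"),
            DeformationField(zero.disp.copy(), "FU->BL"),
            DeformationField(zero.disp.copy(), "BL->FU:forward"),
        )
    grid = _sample_grid(shape)

    if atrophy.mode == "radial" and atrophy.true_bvl_percent != 0:
        kappa = _kappa(spec)
        amp = radial_profile_amplitude(kappa, atrophy.true_bvl_percent)
    else:
        amp = 0.0

    def atrophy_fwd(y):
        r = np.linalg.norm(y, axis=-1)
        out = y.copy()
        if atrophy.mode == "radial":
            inside = (r < 1.0) & (r > 0)
            fac = _radial_g(r[inside], amp) / r[inside]
            out[inside] = y[inside] * fac[:, None]
        else:  # uniform-scale: brain compartment scaled by sigma, identity outside TIV
            sigma = (1.0 + atrophy.true_bvl_percent / 100.0) ** (1.0 / 3.0)
            fac = np.where(r <= 1.0, sigma, 1.0)
            out = y * fac[..., None]
        return out

    def atrophy_inv(y):
        r = np.linalg.norm(y, axis=-1)
        out = y.copy()
        if atrophy.mode == "radial":
            inside = (r < 1.0) & (r > 0)
            fac = _radial_g_inverse(r[inside], amp) / r[inside]
            out[inside] = y[inside] * fac[:, None]
        else:
            sigma = (1.0 + atrophy.true_bvl_percent / 100.0) ** (1.0 / 3.0)
            r_safe = np.maximum(r, 1e-12)
            # inside shrunken brain: invert the scaling; on the created CSF rim
            # [sigma, 1] the continuous choice samples the TIV surface (src = 1)
            src_r = np.where(r <= sigma, r / sigma, np.where(r <= 1.0, 1.0, r))
            out = y * (src_r / r_safe)[..., None]
            out[r <= 1e-12] = 0.0
        return out

    y_grid = (grid - c_vox) / a_vox
    # forward map: distortion(atrophy(x)); fields in voxel units
    fwd_pos = (atrophy_fwd(y_grid) * a_vox + c_vox - c_vox) * s + c_vox
    fwd = fwd_pos - grid
    # pull field for BL->FU warp: phi^{-1} evaluated on the FU grid
    y_undistort = ((grid - c_vox) / s) / a_vox
    pull_pos = atrophy_inv(y_undistort) * a_vox + c_vox
    pull_fw = pull_pos - grid
    # pull field for FU->BL warp: phi evaluated on the BL grid
    pull_bw = fwd.copy()
    return (
        DeformationField(pull_fw.astype(np.float32), "BL->FU"),
        DeformationField(pull_bw.astype(np.float32), "FU->BL"),
        DeformationField(fwd.astype(np.float32), "BL->FU:forward"),
    )


def make_followup(baseline: Volume3D, spec: PhantomSpec, atrophy: AtrophySpec):
    """Render the follow-up volume and the exact :class:`PhantomTruth`.

    The follow-up is the baseline geometry pushed through (i) the analytic
    atrophy map, (ii) the global distortion scale about the grid center, then
    (iii) fresh additive noise.  Because every step maps ellipsoids to
    ellipsoids, the FU image is re-rendered analytically (no resampling
    error) and all truth quantities are closed-form.
    """
    spec.validate()
    atrophy.validate()
    s = atrophy.distortion_scale
    t = atrophy.true_bvl_percent / 100.0
    skull = np.asarray(spec.skull_radii_mm)
    tiv = np.asarray(spec.tiv_radii_mm)
    vent = np.asarray(spec.ventricle_radii_mm)

    if atrophy.mode == "radial":
        if t != 0:
            kappa = _kappa(spec)
            amp = radial_profile_amplitude(kappa, atrophy.true_bvl_percent)
            vent_fu = tiv * float(_radial_g(np.asarray([kappa]), amp)[0])
        else:
            vent_fu = vent.copy()
        brain_fu = tiv.copy()
    else:
        sigma = (1.0 + t) ** (1.0 / 3.0)
        vent_fu = vent * sigma
        brain_fu = tiv * sigma

    img = _render(spec, skull * s, tiv * s, brain_fu * s, vent_fu * s)
    rng = np.random.default_rng([spec.seed, atrophy.seed, 1])
    img = _add_noise(img, spec.noise_sigma, spec.rician, rng)

    args = (spec.grid_size, spec.voxel_mm, spec.center_mm)
    tiv_fu_mask = ellipsoid_mask(*args, tiv * s)
    if np.all(vent_fu > 0):
        vent_fu_mask = ellipsoid_mask(*args, vent_fu * s)
    else:
        vent_fu_mask = np.zeros(spec.grid_size, dtype=np.uint8)
    brain_fu_mask = ellipsoid_mask(*args, brain_fu * s)
    par_fu_mask = (brain_fu_mask.astype(bool) & ~vent_fu_mask.astype(bool)).astype(np.uint8)

    _, par_bl, tiv_bl = make_baseline(dataclasses.replace(spec, noise_sigma=0.0))

    bpv_bl = _ellipsoid_volume(tiv) - _ellipsoid_volume(vent)
    tiv_bl_v = _ellipsoid_volume(tiv)
    field_fw, field_bw, field_forward = _true_fields(spec, atrophy)
    aff = spec.affine
    truth = PhantomTruth(
        bpv_bl_mm3=bpv_bl,
        bpv_fu_mm3=bpv_bl * (1.0 + t) * s**3,
        tiv_bl_mm3=tiv_bl_v,
        tiv_fu_mm3=tiv_bl_v * s**3,
        true_bvl_percent=atrophy.true_bvl_percent,
        distortion_scale=s,
        true_field=field_fw,
        true_field_bw=field_bw,
        true_field_forward=field_forward,
        masks={
            "bl_parenchyma": par_bl,
            "bl_tiv": tiv_bl,
            "fu_parenchyma": Volume3D(par_fu_mask, aff),
            "fu_tiv": Volume3D(tiv_fu_mask, aff),
        },
    )
    return Volume3D(img, aff), truth


@dataclass
class PhantomPair:
    """One in-memory BL/FU pair with its ground truth."""

    bl: Volume3D
    fu: Volume3D
    truth: PhantomTruth
    spec: PhantomSpec
    atrophy: AtrophySpec


def make_pair(spec: PhantomSpec, atrophy: AtrophySpec) -> PhantomPair:
    bl, _, _ = make_baseline(spec)
    fu, truth = make_followup(bl, spec, atrophy)
    return PhantomPair(bl=bl, fu=fu, truth=truth, spec=spec, atrophy=atrophy)


def random_spec(base: PhantomSpec, rng: np.random.Generator,
                size_jitter: float = 0.06,
                vent_ratio_range: tuple[float, float] = (0.2, 0.3),
                seed: int | None = None) -> PhantomSpec:
    """Draw per-subject anatomy around ``base``: global head-size scaling in
    ``1 +/- size_jitter`` and a ventricle/TIV radius ratio from
    ``vent_ratio_range`` (kept proportional so the radial atrophy mode stays
    exact)."""
    scale = float(rng.uniform(1.0 - size_jitter, 1.0 + size_jitter))
    ratio = float(rng.uniform(*vent_ratio_range))
    tiv = tuple(float(r) * scale for r in base.tiv_radii_mm)
    return dataclasses.replace(
        base,
        skull_radii_mm=tuple(float(r) * scale for r in base.skull_radii_mm),
        tiv_radii_mm=tiv,
        ventricle_radii_mm=tuple(r * ratio for r in tiv),
        seed=int(rng.integers(0, 2**31 - 1)) if seed is None else seed,
    )


def make_cohort_pairs(
    n_pairs: int,
    seed: int = 0,
    bvl_range: tuple[float, float] = (-2.0, 0.0),
    distortion_range: tuple[float, float] = (1.0, 1.0),
    spec: PhantomSpec | None = None,
    mode: str = "radial",
    size_jitter: float = 0.06,
    zero_change_every: int = 0,
) -> list[PhantomPair]:
    """In-memory cohort with per-subject anatomy jitter (no disk I/O).

    ``zero_change_every=k`` pins every k-th pair to exactly zero change and
    no distortion (anchoring the no-atrophy case, as test-retest pairs do in
    a development cohort); 0 disables.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    base = spec or PhantomSpec()
    rng = np.random.default_rng([seed, 91])
    pairs = []
    for i in range(n_pairs):
        pspec = random_spec(base, rng, size_jitter=size_jitter)
        if zero_change_every and i % zero_change_every == 0:
            bvl, dist = 0.0, 1.0
        else:
            bvl = float(rng.uniform(*bvl_range))
            dist = float(rng.uniform(*distortion_range))
        pairs.append(make_pair(pspec, AtrophySpec(bvl, mode, dist, seed=pspec.seed)))
    return pairs


TRUTH_COLUMNS = [
    "pair_id",
    "true_bvl_percent",
    "distortion_scale",
    "bpv_bl_mm3",
    "bpv_fu_mm3",
    "tiv_bl_mm3",
    "tiv_fu_mm3",
    "seed",
]


def generate_cohort(
    n_pairs: int,
    out_dir,
    seed: int = 0,
    bvl_range: tuple[float, float] = (-2.0, 0.0),
    distortion_range: tuple[float, float] = (1.0, 1.0),
    spec: PhantomSpec | None = None,
    mode: str = "radial",
    size_jitter: float = 0.06,
    save_fields: bool = False,
    save_masks: bool = True,
) -> pd.DataFrame:
    """Write a cohort of BL/FU NIfTI pairs plus a truth table CSV.

    Per-pair BVL and distortion are drawn uniformly from the given ranges
    (degenerate ranges pin the value); everything is reproducible from the
    master ``seed``.  Returns the truth table, also written to
    ``out_dir/truth.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = make_cohort_pairs(
        n_pairs, seed=seed, bvl_range=bvl_range, distortion_range=distortion_range,
        spec=spec, mode=mode, size_jitter=size_jitter,
    )
    rows = []
    for i, pair in enumerate(pairs):
        pspec = pair.spec
        pid = f"pair_{i:04d}"
        pair.bl.save(out_dir / f"{pid}_bl.nii.gz")
        pair.fu.save(out_dir / f"{pid}_fu.nii.gz")
        if save_masks:
            for key, vol in pair.truth.masks.items():
                vol.save(out_dir / f"{pid}_{key}.nii.gz")
        if save_fields:
            pair.truth.true_field.save(out_dir / f"{pid}_field_fw.nii.gz", pspec.affine)
            pair.truth.true_field_bw.save(out_dir / f"{pid}_field_bw.nii.gz", pspec.affine)
        tr = pair.truth
        rows.append(
            dict(
                pair_id=pid,
                true_bvl_percent=tr.true_bvl_percent,
                distortion_scale=tr.distortion_scale,
                bpv_bl_mm3=tr.bpv_bl_mm3,
                bpv_fu_mm3=tr.bpv_fu_mm3,
                tiv_bl_mm3=tr.tiv_bl_mm3,
                tiv_fu_mm3=tr.tiv_fu_mm3,
                seed=pspec.seed,
            )
        )
    table = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    table.to_csv(out_dir / "truth.csv", index=False)
    return table
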