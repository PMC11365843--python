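"""Symmetric mask-warping volumetry, distortion correction and rescaling.

This is the quantitative core of the pipeline.  Per baseline/follow-up (BL/FU)
pair it measures eight volumes -- brain parenchyma volume (BPV) and total
intracranial volume (TIV), each native and warped, in both registration
directions -- and derives the percentage brain volume loss (BVL):

* forward change   ``dBPV_fw = 100 * (BPV_FU<-BL - BPV_BL) / BPV_BL``
* backward change  ``dBPV_bw = 100 * (BPV_FU - BPV_BL<-FU) / BPV_BL<-FU``
  (the denominator is deliberately the warped-to-BL volume)
* symmetric mean   ``dBPV = 0.5 * (dBPV_fw + dBPV_bw)``, likewise ``dTIV``
* distortion correction ``res_dBPV = dBPV - m_tiv * dTIV`` -- the apparent
  TIV change proxies scanner-distortion severity, which inflates BPV and TIV
  alike; the regression intercept is *not* subtracted (it represents the mean
  atrophy of the calibration cohort, not distortion)
* rescaling ``BVL = res_dBPV / m_siena`` so the corrected residual is on the
  percent scale of the reference method used for calibration.

Negative BVL denotes loss throughout.

Warped volumes are *soft*: a binary mask pull-warped with trilinear
interpolation keeps fractional boundary values, and the volume is the plain
sum of voxel values times the voxel volume -- no re-thresholding.  A
Jacobian-determinant integration oracle is included as the independent route
to volume change from a deformation field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .registration.fields import DeformationField, warp
from .volume import Volume3D


class DegenerateInputError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


# Calibration constants derived from the published training-cohort
# regressions (slope of dBPV on dTIV; rescaling slope against the reference
# surface-based BVL method).  Intercepts are recorded but unused.
PUBLISHED_DEFAULT = dict(m_tiv=0.95, c_tiv=-0.23, m_siena=0.30, c_siena=-0.01)


@dataclass(frozen=True)
class CalibrationParams:
    """Regression constants of the distortion-correction and rescaling steps."""

    m_tiv: float = PUBLISHED_DEFAULT["m_tiv"]
    c_tiv: float = PUBLISHED_DEFAULT["c_tiv"]
    m_siena: float = PUBLISHED_DEFAULT["m_siena"]
    c_siena: float = PUBLISHED_DEFAULT["c_siena"]
    provenance: str = "published-default"

    def __post_init__(self) -> None:
        if self.m_siena == 0:
            raise CalibrationError("m_siena must be nonzero")

    @classmethod
    def unit(cls) -> "CalibrationParams":
        """TIV slope from the published calibration, but no rescaling --
        appropriate when ground truth (not a reference method) is the anchor."""
        return cls(m_siena=1.0, c_siena=0.0, provenance="unit-rescaling")

    def to_yaml(self, path) -> None:
        payload = {
            "m_tiv": float(self.m_tiv),
            "c_tiv": float(self.c_tiv),
            "m_siena": float(self.m_siena),
            "c_siena": float(self.c_siena),
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationParams":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**{k: payload[k] for k in ("m_tiv", "c_tiv", "m_siena", "c_siena", "provenance")})


@dataclass
class PairVolumes:
    """The eight measured volumes (mm^3) of one BL/FU pair."""

    bpv_bl: float
    bpv_fu: float
    bpv_fu_from_bl: float
    bpv_bl_from_fu: float
    tiv_bl: float
    tiv_fu: float
    tiv_fu_from_bl: float
    tiv_bl_from_fu: float

    def validate(self) -> None:
        vals = [
            self.bpv_bl, self.bpv_fu, self.bpv_fu_from_bl, self.bpv_bl_from_fu,
            self.tiv_bl, self.tiv_fu, self.tiv_fu_from_bl, self.tiv_bl_from_fu,
        ]
        if any(v <= 0 for v in vals):
            raise DegenerateInputError("all measured volumes must be positive")
        for native, warped, name in (
            (self.bpv_bl, self.bpv_fu_from_bl, "BPV fw"),
            (self.bpv_fu, self.bpv_bl_from_fu, "BPV bw"),
            (self.tiv_bl, self.tiv_fu_from_bl, "TIV fw"),
            (self.tiv_fu, self.tiv_bl_from_fu, "TIV bw"),
        ):
            if abs(warped - native) > 0.2 * native:
                raise DegenerateInputError(
                    f"{name}: warped volume {warped:.0f} deviates >20% from native "
                    f"{native:.0f} -- registration or segmentation failure"
                )


@dataclass
class BVLResult:
    """All derived per-pair quantities (percent; negative = loss)."""

    dbpv_fw: float
    dbpv_bw: float
    dbpv: float
    dtiv_fw: float
    dtiv_bw: float
    dtiv: float
    res_dbpv: float
    bvl_fw: float
    bvl_bw: float
    bvl: float
    volumes: PairVolumes | None = None
    calibration: CalibrationParams | None = None

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "dbpv_fw", "dbpv_bw", "dbpv", "dtiv_fw", "dtiv_bw", "dtiv",
                "res_dbpv", "bvl_fw", "bvl_bw", "bvl",
            )
        }
        return {k: float(v) for k, v in d.items()}


# --- volume measurement ------------------------------------------------------


def mask_volume(mask, voxel_mm3: float | None = None) -> float:
    """Volume of a binary mask: nonzero-voxel count times voxel volume."""
    if isinstance(mask, Volume3D):
        data, vv = mask.data, mask.voxel_volume_mm3
    else:
        data, vv = np.asarray(mask), float(voxel_mm3 if voxel_mm3 is not None else 1.0)
    count = int(np.count_nonzero(data))
    if count == 0:
        raise DegenerateInputError("empty mask")
    return count * vv


def soft_volume(warped_mask, voxel_mm3: float | None = None, eps: float = 1e-3) -> float:
    """Volume of a warped (fractional) mask: sum of voxel values times voxel volume.

    Boundary voxels with values in (0, 1) contribute fractionally; values are
    required to lie in [-eps, 1 + eps].
    """
    if isinstance(warped_mask, Volume3D):
        data, vv = warped_mask.data, warped_mask.voxel_volume_mm3
    else:
        data, vv = np.asarray(warped_mask), float(voxel_mm3 if voxel_mm3 is not None else 1.0)
    if float(data.min()) < -eps or float(data.max()) > 1.0 + eps:
        raise ValueError("soft mask values must lie in [0, 1] (within tolerance)")
    return float(data.sum(dtype=np.float64)) * vv


# --- the change formulas -----------------------------------------------------


def delta_fw(v_native_bl: float, v_warped_to_fu: float) -> float:
    """Forward percentage change: 100 * (V_FU<-BL - V_BL) / V_BL."""
    if v_native_bl == 0:
        raise DegenerateInputError("native BL volume is zero")
    return 100.0 * (v_warped_to_fu - v_native_bl) / v_native_bl


def delta_bw(v_native_fu: float, v_warped_to_bl: float) -> float:
    """Backward percentage change: 100 * (V_FU - V_BL<-FU) / V_BL<-FU.

    The denominator is the warped-to-BL volume (the backward estimate of the
    baseline volume), implemented literally as defined.
    """
    if v_warped_to_bl == 0:
        raise DegenerateInputError("warped-to-BL volume is zero")
    return 100.0 * (v_native_fu - v_warped_to_bl) / v_warped_to_bl


def symmetric_mean(d_fw: float, d_bw: float) -> float:
    """Average of forward and backward estimates (reduces asymmetry bias)."""
    return 0.5 * (d_fw + d_bw)


def distortion_correct(dbpv: float, dtiv: float, cal: CalibrationParams) -> float:
    """Residual of dBPV w.r.t. the dTIV regression line; intercept not subtracted."""
    return dbpv - cal.m_tiv * dtiv


def rescale(res_dbpv: float, cal: CalibrationParams) -> float:
    """Rescale the corrected residual to percent BVL: res_dBPV / m_siena."""
    if cal.m_siena == 0:
        raise CalibrationError("m_siena must be nonzero")
    return res_dbpv / cal.m_siena


# --- per-pair driver ---------------------------------------------------------


def compute_pair_from_volumes(vols: PairVolumes, cal: CalibrationParams) -> BVLResult:
    """Derive every BVL quantity from the eight measured volumes."""
    vols.validate()
    dbpv_fw = delta_fw(vols.bpv_bl, vols.bpv_fu_from_bl)
    dbpv_bw = delta_bw(vols.bpv_fu, vols.bpv_bl_from_fu)
    dtiv_fw = delta_fw(vols.tiv_bl, vols.tiv_fu_from_bl)
    dtiv_bw = delta_bw(vols.tiv_fu, vols.tiv_bl_from_fu)
    dbpv = symmetric_mean(dbpv_fw, dbpv_bw)
    dtiv = symmetric_mean(dtiv_fw, dtiv_bw)
    res_dbpv = distortion_correct(dbpv, dtiv, cal)
    bvl_fw = dbpv_fw - cal.m_tiv * dtiv_fw
    bvl_bw = dbpv_bw - cal.m_tiv * dtiv_bw
    # final estimate, written in the per-direction form so the identity
    # bvl == 0.5 * (bvl_fw + bvl_bw) / m_siena holds bit-exact
    bvl = 0.5 * (bvl_fw + bvl_bw) / cal.m_siena
    return BVLResult(
        dbpv_fw=dbpv_fw, dbpv_bw=dbpv_bw, dbpv=dbpv,
        dtiv_fw=dtiv_fw, dtiv_bw=dtiv_bw, dtiv=dtiv,
        res_dbpv=res_dbpv, bvl_fw=bvl_fw, bvl_bw=bvl_bw, bvl=bvl,
        volumes=vols, calibration=cal,
    )


def measure_pair_volumes(
    bl_parenchyma: Volume3D,
    fu_parenchyma: Volume3D,
    bl_tiv: Volume3D,
    fu_tiv: Volume3D,
    field_fw: DeformationField,
    field_bw: DeformationField,
) -> PairVolumes:
    """Fill the eight volumes by mask counting plus soft-warp summation.

    ``field_fw`` warps BL-space masks onto the FU crop; ``field_bw`` the
    reverse (both pull-convention).
    """
    vv = bl_parenchyma.voxel_volume_mm3

    def softwarp(mask: Volume3D, fld: DeformationField) -> float:
        return soft_volume(np.clip(warp(mask.data.astype(np.float32), fld), 0.0, 1.0), vv)

    return PairVolumes(
        bpv_bl=mask_volume(bl_parenchyma),
        bpv_fu=mask_volume(fu_parenchyma),
        bpv_fu_from_bl=softwarp(bl_parenchyma, field_fw),
        bpv_bl_from_fu=softwarp(fu_parenchyma, field_bw),
        tiv_bl=mask_volume(bl_tiv),
        tiv_fu=mask_volume(fu_tiv),
        tiv_fu_from_bl=softwarp(bl_tiv, field_fw),
        tiv_bl_from_fu=softwarp(fu_tiv, field_bw),
    )


def compute_pair(
    bl_parenchyma: Volume3D,
    fu_parenchyma: Volume3D,
    bl_tiv: Volume3D,
    fu_tiv: Volume3D,
    field_fw: DeformationField,
    field_bw: DeformationField,
    cal: CalibrationParams | None = None,
) -> BVLResult:
    """Full symmetric mask-warping volumetry for one preprocessed pair."""
    cal = cal or CalibrationParams()
    vols = measure_pair_volumes(bl_parenchyma, fu_parenchyma, bl_tiv, fu_tiv, field_fw, field_bw)
    return compute_pair_from_volumes(vols, cal)


# --- calibration fits --------------------------------------------------------


def _ols_fit(y, x, min_n: int = 3):
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if len(y) < min_n:
        raise DegenerateInputError(f"need >= {min_n} pairs")
    if np.ptp(x) == 0:
        raise DegenerateInputError("predictor has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    slope, intercept = float(model.params[1]), float(model.params[0])
    return slope, intercept, (float(ci[1][0]), float(ci[1][1])), (float(ci[0][0]), float(ci[0][1]))


def fit_tiv_regression(dbpv_list, dtiv_list):
    """OLS of dBPV on dTIV over a calibration cohort.

    Returns ``(m_tiv, c_tiv, slope_ci, intercept_ci)`` with 95% CIs.
    """
    slope, intercept, s_ci, i_ci = _ols_fit(dbpv_list, dtiv_list)
    return slope, intercept, s_ci, i_ci


def fit_rescale_regression(res_list, reference_bvl_list):
    """OLS of the corrected residual on a reference BVL estimate.

    Only the slope is used downstream (it rescales residuals to percent BVL);
    the intercept and CIs are reported for provenance.
    """
    slope, intercept, s_ci, i_ci = _ols_fit(res_list, reference_bvl_list)
    return slope, intercept, s_ci, i_ci


def calibrate(dbpv, dtiv, res_reference_bvl=None, provenance: str = "refit") -> CalibrationParams:
    """Refit both regressions on a cohort and return packaged parameters.

    ``res_reference_bvl`` is the reference BVL (an external estimate, or
    phantom ground truth); when omitted, rescaling stays at 1 (unit).
    """
    m_tiv, c_tiv, _, _ = fit_tiv_regression(dbpv, dtiv)
    if res_reference_bvl is not None:
        res = np.asarray(dbpv, float) - m_tiv * np.asarray(dtiv, float)
        m_s, c_s, _, _ = fit_rescale_regression(res, res_reference_bvl)
    else:
        m_s, c_s = 1.0, 0.0
    return CalibrationParams(m_tiv=m_tiv, c_tiv=c_tiv, m_siena=m_s, c_siena=c_s,
                             provenance=provenance)


# --- Jacobian-determinant integration oracle ---------------------------------


def jacobian_integration(field: DeformationField, mask) -> float:
    """Percent volume change by integrating det(I + grad u) over a mask.

    ``field`` must carry *forward* (Lagrangian) displacements in voxels on
    the mask's grid; the gradient is taken by central differences.  Serves as
    the independent oracle against soft-mask-warp volumetry.  Voxels with
    non-positive determinant (folding) are counted and reported as a warning.
    """
    data = mask.data if isinstance(mask, Volume3D) else np.asarray(mask)
    if data.shape != field.shape:
        raise ValueError("field and mask must share a grid")
    m = data.astype(bool)
    if not m.any():
        raise DegenerateInputError("empty mask")
    u = field.disp.astype(np.float64)
    jac = np.empty(field.shape + (3, 3))
    for i in range(3):
        grads = np.gradient(u[..., i], axis=(0, 1, 2))
        for j in range(3):
            jac[..., i, j] = grads[j]
    jac[..., 0, 0] += 1.0
    jac[..., 1, 1] += 1.0
    jac[..., 2, 2] += 1.0
    det = np.linalg.det(jac[m])
    n_fold = int(np.count_nonzero(det <= 0))
    if n_fold:
        warnings.warn(f"jacobian_integration: {n_fold} voxels with non-positive determinant "
                      "(field folding)", RuntimeWarning, stacklevel=2)
    return 100.0 * float(det.mean() - 1.0)
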