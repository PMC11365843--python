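"""Phantom study drivers: the package's self-contained validation experiments.

Each function runs one experiment end to end on synthetic cohorts with exact
ground truth and returns plain dictionaries/tables of measured quantities:

* ground-truth recovery with exact (oracle) deformation fields;
* efficacy of the TIV-based distortion correction on zero-atrophy pairs;
* equivalence of soft-mask-warp volumetry and Jacobian-determinant
  integration on analytic fields;
* the symmetric-estimate identity and BL/FU swap antisymmetry;
* recovery of calibration regression slopes on simulated cohorts;
* calibration of the statistical machinery (Pitman test size, ICC);
* desk-scale training of the registration network plus rescaling
  calibration and held-out evaluation.

All randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .evaluation import icc_absolute, pitman_test
from .phantom import AtrophySpec, PhantomSpec, make_cohort_pairs, make_pair, random_spec
from .preprocess import normalize_crop
from .registration.backends import UNetBackend, predict_field
from .registration.fields import radial_atrophy_field, uniform_scale_field, warp
from .registration.train import train_registration
from .registration.unet import RegistrationConfig
from .volumetry import (
    CalibrationParams,
    compute_pair,
    fit_rescale_regression,
    fit_tiv_regression,
    jacobian_integration,
    mask_volume,
    soft_volume,
)

log = logging.getLogger(__name__)


def measure_with_truth(pair, cal: CalibrationParams, backend=None):
    """Volumetry of one phantom pair using its truth masks.

    Fields come from ``backend`` (applied to normalized crops) or, when
    omitted, from the phantom's exact fields.
    """
    tr = pair.truth
    if backend is None:
        field_fw, field_bw = tr.true_field, tr.true_field_bw
    else:
        na = normalize_crop(pair.bl).data
        nb = normalize_crop(pair.fu).data
        field_fw = predict_field(backend, na, nb)
        field_bw = predict_field(backend, nb, na)
    return compute_pair(
        tr.masks["bl_parenchyma"], tr.masks["fu_parenchyma"],
        tr.masks["bl_tiv"], tr.masks["fu_tiv"], field_fw, field_bw, cal,
    )


# --- oracle-field ground-truth recovery --------------------------------------


def oracle_recovery_study(
    seed: int = 0,
    bvl_levels=(0.0, -0.5, -1.0, -2.0),
    n_per_level: int = 5,
    spec: PhantomSpec | None = None,
) -> pd.DataFrame:
    """Noise-free pairs with exact fields: how exactly does mask-warping
    volumetry recover known BVL?  Unit rescaling (truth needs no rescale)."""
    base = spec or PhantomSpec()
    cal = CalibrationParams.unit()
    rng = np.random.default_rng([seed, 11])
    rows = []
    for bvl in bvl_levels:
        for _ in range(n_per_level):
            pspec = random_spec(base, rng)
            pair = make_pair(pspec, AtrophySpec(bvl, "radial", 1.0, seed=pspec.seed))
            res = measure_with_truth(pair, cal)
            rows.append(dict(true_bvl=bvl, est_bvl=res.bvl, error=res.bvl - bvl))
    return pd.DataFrame(rows)


# --- distortion-correction efficacy ------------------------------------------


def distortion_robustness_study(
    seed: int = 0,
    n_pairs: int = 100,
    distortion_range=(0.997, 1.003),
    spec: PhantomSpec | None = None,
) -> dict:
    """Zero-atrophy pairs with random global distortion: compare the spread
    of corrected estimates against uncorrected dBPV (the robustness analogue,
    with a Pitman paired-variance test)."""
    cal = CalibrationParams.unit()  # m_tiv = 0.95, no rescale
    pairs = make_cohort_pairs(
        n_pairs, seed=seed, bvl_range=(0.0, 0.0), distortion_range=distortion_range,
        spec=spec,
    )
    uncorrected = []
    corrected = []
    for pair in pairs:
        res = measure_with_truth(pair, cal)
        uncorrected.append(res.dbpv)
        corrected.append(res.bvl)
    uncorrected = np.asarray(uncorrected)
    corrected = np.asarray(corrected)
    pit = pitman_test(uncorrected, corrected, method="spearman")
    return {
        "n": n_pairs,
        "sd_uncorrected": float(uncorrected.std(ddof=1)),
        "sd_corrected": float(corrected.std(ddof=1)),
        "sd_ratio": float(corrected.std(ddof=1) / uncorrected.std(ddof=1)),
        "pitman_correlation": pit.correlation,
        "pitman_p": pit.p_value,
        "mean_corrected": float(corrected.mean()),
    }


# --- mask warping vs Jacobian integration ------------------------------------


def oracle_equivalence_study(grid_sizes=(64, 128), spec: PhantomSpec | None = None) -> dict:
    """Soft-mask-warp volume change vs Jacobian-determinant integration on
    analytic uniform-scale and radial fields, at one or more resolutions."""
    base = spec or PhantomSpec()
    out: dict = {"cases": []}
    for n in grid_sizes:
        factor = n / base.grid_size[0]
        pspec = dataclasses.replace(
            base, grid_size=(n,) * 3, voxel_mm=base.voxel_mm / factor,
        )
        from .phantom import make_baseline

        _, par, _ = make_baseline(pspec)
        vv = par.voxel_volume_mm3
        v0 = mask_volume(par)
        tiv_vox = np.asarray(pspec.tiv_radii_mm) / pspec.voxel_mm
        kappa = pspec.ventricle_radii_mm[0] / pspec.tiv_radii_mm[0]
        cases = [
            ("uniform-0.99", uniform_scale_field((n,) * 3, 0.99, "pull"),
             uniform_scale_field((n,) * 3, 0.99, "forward"), 100 * (0.99**3 - 1)),
            ("uniform-1.01", uniform_scale_field((n,) * 3, 1.01, "pull"),
             uniform_scale_field((n,) * 3, 1.01, "forward"), 100 * (1.01**3 - 1)),
            ("radial-1pct", radial_atrophy_field((n,) * 3, tiv_vox, kappa, -1.0, "pull"),
             radial_atrophy_field((n,) * 3, tiv_vox, kappa, -1.0, "forward"), -1.0),
            ("radial-3pct", radial_atrophy_field((n,) * 3, tiv_vox, kappa, -3.0, "pull"),
             radial_atrophy_field((n,) * 3, tiv_vox, kappa, -3.0, "forward"), -3.0),
        ]
        for name, f_pull, f_fwd, closed in cases:
            mw = 100.0 * (soft_volume(np.clip(warp(par.data.astype(np.float32), f_pull), 0, 1), vv) / v0 - 1.0)
            ji = jacobian_integration(f_fwd, par)
            out["cases"].append(dict(grid=n, case=name, mask_warp=mw, jacobian=ji,
                                     closed_form=closed, gap=abs(mw - ji)))
    df = pd.DataFrame(out["cases"])
    out["max_gap_by_grid"] = {int(g): float(df[df.grid == g].gap.max())
                              for g in df.grid.unique()}
    return out


# --- symmetric-estimate identity and swap antisymmetry -----------------------


def symmetry_study(seed: int = 0, n_pairs: int = 4, spec: PhantomSpec | None = None) -> dict:
    """Per-direction identity (final estimate == half-sum of per-direction
    estimates over the rescaling slope) and BL/FU swap antisymmetry."""
    base = spec or PhantomSpec()
    cal = CalibrationParams()  # published constants, incl. m_siena = 0.30
    rng = np.random.default_rng([seed, 13])
    identity_dev = []
    antisym_dev = []
    for _ in range(n_pairs):
        pspec = random_spec(base, rng)
        bvl = float(rng.uniform(-2.0, -0.3))
        pair = make_pair(pspec, AtrophySpec(bvl, "radial", 1.0, seed=pspec.seed))
        res = measure_with_truth(pair, cal)
        identity_dev.append(abs(res.bvl - 0.5 * (res.bvl_fw + res.bvl_bw) / cal.m_siena))
        tr = pair.truth
        swapped = compute_pair(
            tr.masks["fu_parenchyma"], tr.masks["bl_parenchyma"],
            tr.masks["fu_tiv"], tr.masks["bl_tiv"],
            tr.true_field_bw, tr.true_field, cal,
        )
        antisym_dev.append(abs(swapped.bvl + res.bvl) * cal.m_siena)
    return {
        "n": n_pairs,
        "max_identity_deviation": float(max(identity_dev)),
        "max_antisymmetry_deviation_pct": float(max(antisym_dev)),
    }


# --- calibration-fit recovery ------------------------------------------------


def calibration_recovery_study(seed: int = 0, n_reps: int = 100, n: int = 200) -> dict:
    """OLS slope recovery on simulated calibration cohorts.

    Noisy cohorts: dBPV = 0.9 dTIV + N(0, 0.05) and res = 0.3 ref + N(0, 0.02);
    count how often the 95% CI covers the generating slope.  Noiseless lines
    at the published constants must be recovered to machine precision.
    """
    rng = np.random.default_rng([seed, 23])
    cover_tiv = cover_res = 0
    for _ in range(n_reps):
        dtiv = rng.normal(0.0, 0.5, n)
        dbpv = 0.9 * dtiv + rng.normal(0.0, 0.05, n)
        _, _, ci, _ = fit_tiv_regression(dbpv, dtiv)
        cover_tiv += ci[0] <= 0.9 <= ci[1]
        ref = rng.normal(0.0, 1.0, n)
        res = 0.3 * ref + rng.normal(0.0, 0.02, n)
        _, _, ci, _ = fit_rescale_regression(res, ref)
        cover_res += ci[0] <= 0.3 <= ci[1]
    x = np.linspace(-2, 2, 50)
    m1, c1, _, _ = fit_tiv_regression(0.95 * x - 0.23, x)
    m2, c2, _, _ = fit_rescale_regression(0.30 * x - 0.01, x)
    return {
        "n_reps": n_reps,
        "coverage_tiv": int(cover_tiv),
        "coverage_rescale": int(cover_res),
        "noiseless_m_tiv": float(m1),
        "noiseless_c_tiv": float(c1),
        "noiseless_m_rescale": float(m2),
        "noiseless_c_rescale": float(c2),
    }


# --- statistical machinery calibration ---------------------------------------


def statistics_calibration_study(seed: int = 0, n_reps: int = 1000, n: int = 200,
                                 alpha: float = 0.05) -> dict:
    """Type-I error of the Pitman test under the equal-variance null (both
    correlation methods) and ICC against its closed form under the
    truth-plus-noise model."""
    rng = np.random.default_rng([seed, 31])
    rej = {"pearson": 0, "spearman": 0}
    for _ in range(n_reps):
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(0.0, 1.0, n)
        for method in rej:
            if pitman_test(a, b, method=method).p_value < alpha:
                rej[method] += 1
    sd_truth, sigma, n_icc = 1.0, 0.1, 500
    truth = rng.normal(0.0, sd_truth, n_icc)
    x = truth + rng.normal(0.0, sigma, n_icc)
    y = truth + rng.normal(0.0, sigma, n_icc)
    icc = icc_absolute(x, y)
    icc_closed = sd_truth**2 / (sd_truth**2 + sigma**2)
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "type1_pearson": rej["pearson"] / n_reps,
        "type1_spearman": rej["spearman"] / n_reps,
        "icc": float(icc),
        "icc_closed_form": float(icc_closed),
        "icc_abs_dev": float(abs(icc - icc_closed)),
    }


# --- trained-backend study ----------------------------------------------------


def train_desk_backend(seed: int = 1, n_train: int = 16, epochs: int = 40,
                       spec: PhantomSpec | None = None):
    """Train the registration U-Net on a desk-scale jittered phantom cohort.

    The cohort mixes atrophy in [-3, 0]% with mild distortion and anchors
    every fourth pair at exactly zero change (test-retest analogue).
    Returns ``(backend, training_pairs, history)``.
    """
    train_pairs = make_cohort_pairs(
        n_train, seed=seed * 1000 + 1, bvl_range=(-3.0, 0.0),
        distortion_range=(0.997, 1.003), zero_change_every=4, spec=spec,
    )
    crops = [(normalize_crop(p.bl).data, normalize_crop(p.fu).data) for p in train_pairs]
    cfg = RegistrationConfig(epochs=epochs, seed=seed)
    model, history = train_registration(crops, cfg)
    return UNetBackend(model), train_pairs, history


def fit_rescale_for_backend(backend, train_pairs) -> CalibrationParams:
    """Rescaling calibration for a trained backend (truth as reference).

    Keeps the distortion-correction slope at its published value and refits
    only the rescaling slope by regressing the corrected residual on the
    ground-truth BVL over the training cohort -- the phantom stand-in for the
    reference-method regression.
    """
    unit = CalibrationParams.unit()
    res_list, ref = [], []
    for pair in train_pairs:
        r = measure_with_truth(pair, unit, backend=backend)
        res_list.append(r.res_dbpv)
        ref.append(pair.truth.true_bvl_percent)
    m_s, c_s, _, _ = fit_rescale_regression(res_list, ref)
    return CalibrationParams(m_tiv=0.95, c_tiv=0.0, m_siena=m_s, c_siena=c_s,
                             provenance="phantom-rescale-fit")


def trained_backend_study(
    backend,
    cal: CalibrationParams,
    seed: int = 1,
    heldout_bvl=(-0.5, -1.0, -2.0, 1.0, -1.5, -2.5),
    spec: PhantomSpec | None = None,
) -> dict:
    """Held-out evaluation of a trained backend: self-registration field
    magnitude, sign correctness on +/-1% pairs, and absolute BVL error on
    held-out noise-free pairs."""
    base = spec or PhantomSpec()
    rng = np.random.default_rng([seed, 77])
    spec0 = random_spec(base, rng)
    p0 = make_pair(spec0, AtrophySpec(0.0, "radial", 1.0, seed=spec0.seed))
    a = normalize_crop(p0.bl).data
    self_reg = float(np.abs(predict_field(backend, a, a).disp).mean())
    rows = []
    for bvl in heldout_bvl:
        pspec = random_spec(base, rng)
        pair = make_pair(pspec, AtrophySpec(bvl, "radial", 1.0, seed=pspec.seed))
        est = measure_with_truth(pair, cal, backend=backend).bvl
        rows.append(dict(true_bvl=bvl, est_bvl=est, error=est - bvl))
    df = pd.DataFrame(rows)
    signs = df[np.isclose(np.abs(df.true_bvl), 1.0)]
    return {
        "self_registration_mean_disp_vox": self_reg,
        "heldout": df,
        "max_abs_error": float(df.error.abs().max()),
        "signs_correct": bool((np.sign(signs.est_bvl) == np.sign(signs.true_bvl)).all()),
        "m_rescale": cal.m_siena,
    }
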