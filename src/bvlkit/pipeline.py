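"""End-to-end orchestration: NIfTI pair in, BVL result out.

``run_pair`` performs the full chain -- reslice, head crop, rigid halfway
alignment, segmentation (or external masks), deformable registration in both
directions, symmetric mask-warping volumetry with distortion correction and
rescaling.  ``process_cohort`` maps it over a simulated cohort directory and
collects a results table for calibration and evaluation.

All stages after the halfway alignment operate in crop-local coordinates
(isotropic spacing, origin at the crop corner); displacement fields are in
voxels of that frame.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import (
    apply_crop,
    head_crop_box,
    normalize_crop,
    reslice_isotropic,
    resample_mask_like,
    rigid_register_halfway,
)
from .registration.backends import RegistrationBackend, predict_field
from .registration.fields import DeformationField
from .segment import otsu_segmenter
from .volume import Volume3D
from .volumetry import BVLResult, CalibrationParams, compute_pair

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a pipeline run (recorded in every output)."""

    crop_shape: tuple[int, int, int] = (64, 64, 64)
    target_mm: float = 1.0
    do_reslice: bool = True
    do_crop: bool = True
    do_rigid: bool = True
    rigid_metric: str = "ncc"
    segmenter: str = "external-masks"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _local_frame(vol: Volume3D, target_mm: float) -> Volume3D:
    """Rebase a crop onto the crop-local frame (diagonal affine, origin 0)."""
    return Volume3D(vol.data, np.diag([target_mm] * 3 + [1.0]))


def preprocess_pair(bl: Volume3D, fu: Volume3D, config: RunConfig,
                    bl_masks: tuple[Volume3D, Volume3D] | None = None,
                    fu_masks: tuple[Volume3D, Volume3D] | None = None):
    """Reslice, crop and rigidly align a pair (and its masks) into halfway space.

    Returns ``(bl_crop, fu_crop, bl_masks, fu_masks)`` on a common grid.
    Masks travel through the same crop box as their image and through the
    same halfway transform (trilinear, re-thresholded at 0.5).
    """
    def prep(vol, masks):
        if config.do_reslice:
            vol = reslice_isotropic(vol, config.target_mm)
            if masks is not None:
                masks = tuple(
                    Volume3D(
                        (reslice_isotropic(
                            Volume3D(m.data.astype(np.float32), m.affine), config.target_mm
                        ).data >= 0.5).astype(np.uint8),
                        vol.affine,
                    )
                    for m in masks
                )
        if config.do_crop:
            box = head_crop_box(vol, config.crop_shape)
            vol = apply_crop(vol, box, config.crop_shape)
            if masks is not None:
                masks = tuple(apply_crop(m, box, config.crop_shape) for m in masks)
        vol = _local_frame(vol, config.target_mm)
        if masks is not None:
            masks = tuple(_local_frame(m, config.target_mm) for m in masks)
        return vol, masks

    bl, bl_masks = prep(bl, bl_masks)
    fu, fu_masks = prep(fu, fu_masks)

    if config.do_rigid:
        pair = rigid_register_halfway(bl, fu, metric=config.rigid_metric)
        if bl_masks is not None:
            bl_masks = tuple(resample_mask_like(m, pair.half_bl) for m in bl_masks)
        if fu_masks is not None:
            fu_masks = tuple(resample_mask_like(m, pair.half_fu) for m in fu_masks)
        bl, fu = pair.bl_crop, pair.fu_crop
    return bl, fu, bl_masks, fu_masks


def run_pair(
    bl: Volume3D,
    fu: Volume3D,
    backend: RegistrationBackend | None = None,
    fields: tuple[DeformationField, DeformationField] | None = None,
    bl_masks: tuple[Volume3D, Volume3D] | None = None,
    fu_masks: tuple[Volume3D, Volume3D] | None = None,
    cal: CalibrationParams | None = None,
    config: RunConfig | None = None,
) -> BVLResult:
    """Full pipeline for one BL/FU pair.

    ``bl_masks`` / ``fu_masks`` are (parenchyma, TIV) in native space; when
    omitted the fallback segmenter runs on the halfway crops.  Either a
    registration ``backend`` or a precomputed ``fields`` tuple (fw, bw) must
    be given.
    """
    config = config or RunConfig()
    cal = cal or CalibrationParams()
    if backend is None and fields is None:
        raise ValueError("provide a registration backend or precomputed fields")

    t0 = time.time()
    bl_c, fu_c, bl_masks, fu_masks = preprocess_pair(bl, fu, config, bl_masks, fu_masks)
    log.info("preprocessing: %.1fs", time.time() - t0)

    if bl_masks is None or fu_masks is None:
        t0 = time.time()
        seg_bl = otsu_segmenter(bl_c)
        seg_fu = otsu_segmenter(fu_c)
        bl_masks = bl_masks or seg_bl
        fu_masks = fu_masks or seg_fu
        log.info("fallback segmentation: %.1fs", time.time() - t0)

    t0 = time.time()
    if fields is not None:
        field_fw, field_bw = fields
    else:
        bl_n = normalize_crop(bl_c)
        fu_n = normalize_crop(fu_c)
        field_fw = predict_field(backend, bl_n.data, fu_n.data)
        field_bw = predict_field(backend, fu_n.data, bl_n.data)
    log.info("registration: %.1fs", time.time() - t0)

    t0 = time.time()
    result = compute_pair(
        bl_masks[0], fu_masks[0], bl_masks[1], fu_masks[1], field_fw, field_bw, cal
    )
    log.info("volumetry: %.1fs", time.time() - t0)
    return result


def result_payload(result: BVLResult, config: RunConfig, cal: CalibrationParams) -> dict:
    """JSON-ready result with full provenance (version, config, seed)."""
    return {
        "bvlkit_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "calibration": {
            "m_tiv": cal.m_tiv, "c_tiv": cal.c_tiv,
            "m_siena": cal.m_siena, "c_siena": cal.c_siena,
            "provenance": cal.provenance,
        },
        "result": result.to_dict(),
    }


# --- cohort processing -------------------------------------------------------


def load_cohort_pair(cohort_dir: Path, pair_id: str):
    """Load one simulated pair: volumes plus its four ground-truth masks."""
    cohort_dir = Path(cohort_dir)
    bl = Volume3D.load(cohort_dir / f"{pair_id}_bl.nii.gz")
    fu = Volume3D.load(cohort_dir / f"{pair_id}_fu.nii.gz")
    masks = {}
    for key in ("bl_parenchyma", "bl_tiv", "fu_parenchyma", "fu_tiv"):
        p = cohort_dir / f"{pair_id}_{key}.nii.gz"
        masks[key] = Volume3D.load(p) if p.exists() else None
    return bl, fu, masks


def normalized_cohort_crops(cohort_dir, truth: pd.DataFrame):
    """Normalized (bl, fu) crop arrays for every pair (training input)."""
    out = []
    for pair_id in truth["pair_id"]:
        bl, fu, _ = load_cohort_pair(cohort_dir, pair_id)
        out.append((normalize_crop(bl).data, normalize_crop(fu).data))
    return out


def process_cohort(
    cohort_dir,
    backend: RegistrationBackend,
    cal: CalibrationParams | None = None,
    config: RunConfig | None = None,
    use_truth_masks: bool = True,
) -> pd.DataFrame:
    """Run the pipeline over a simulated cohort; returns the per-pair table.

    Simulated pairs are already on a common grid, so reslice/crop/rigid are
    skipped unless the caller's config says otherwise.
    """
    cohort_dir = Path(cohort_dir)
    truth = pd.read_csv(cohort_dir / "truth.csv")
    cal = cal or CalibrationParams()
    config = config or RunConfig(do_reslice=False, do_crop=False, do_rigid=False)
    rows = []
    for pair_id in truth["pair_id"]:
        bl, fu, masks = load_cohort_pair(cohort_dir, pair_id)
        bl_masks = (masks["bl_parenchyma"], masks["bl_tiv"]) if use_truth_masks else None
        fu_masks = (masks["fu_parenchyma"], masks["fu_tiv"]) if use_truth_masks else None
        if use_truth_masks and (bl_masks[0] is None or fu_masks[0] is None):
            raise FileNotFoundError(f"truth masks missing for {pair_id} in {cohort_dir}")
        res = run_pair(bl, fu, backend=backend, bl_masks=bl_masks, fu_masks=fu_masks,
                       cal=cal, config=config)
        row = {"pair_id": pair_id, **res.to_dict(), "m_siena": cal.m_siena}
        rows.append(row)
    return pd.DataFrame(rows)
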