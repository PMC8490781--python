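"""End-to-end orchestration: normalise -> register -> subtract -> segment
-> measure -> report, per case and per cohort."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .grid import ImageGrid
from .io_formats import normalize_to_working, read_image, write_image
from .measurement import (
    ProgressionRecord,
    RoiMeasurement,
    cohort_summary,
    ellipsoid_volume,
    progression,
    rmse,
)
from .registration import register
from .segmentation import segment_abnormality, temporal_features
from .subtraction import colour_code, enhance, subtract

log = logging.getLogger(__name__)

__all__ = ["CaseReport", "run_pipeline", "run_cohort", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class CaseReport:
    patient_id: str
    transform: dict
    residual_rmse: float
    rois: dict  # per timepoint list of ROI feature dicts
    measurements: dict  # per timepoint RoiMeasurement dict
    progression: dict  # dv, direction
    features: dict  # five interval-change features
    outputs: dict  # stage -> written file path
    config: dict
    version: str = __version__

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=_jsonable))
        return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _segment_timepoint(img: ImageGrid, cfg: PipelineConfig):
    """Hierarchical iterative threshold + ROI features for one image."""
    return segment_abnormality(
        img, deltaT=cfg.delta_t, T0=cfg.t0, min_area=cfg.min_area
    )


def _measure_roi(roi, img: ImageGrid, timepoint: str, cfg: PipelineConfig) -> RoiMeasurement:
    length_cm = roi.major_axis / 10.0
    width_cm = roi.minor_axis / 10.0
    height_cm = img.slice_thickness / 10.0
    return RoiMeasurement(
        length=length_cm,
        width=width_cm,
        height=height_cm,
        diameter=roi.feret_diameter / 10.0,
        volume=ellipsoid_volume(length_cm, width_cm, height_cm, cfg.volume_convention),
        timepoint=timepoint,
        method="auto",
        convention=cfg.volume_convention,
    )


def run_pipeline(
    original_path: str | Path,
    current_path: str | Path,
    config: PipelineConfig | None = None,
    patient_id: str = "case",
    write_outputs: bool = True,
) -> CaseReport:
    """Run the full per-case pipeline and return its report.

    Stages: read + normalise both images, register the current image onto
    the original, subtract and colour-code, segment both registered
    images, measure the dominant ROI at each timepoint, and compute the
    interval volume change.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    cfg = config or PipelineConfig()
    outdir = Path(cfg.output_dir) / patient_id
    outputs: dict[str, str] = {}

    try:
        geometry = dict(
            pixel_spacing=cfg.pixel_spacing_mm, slice_thickness=cfg.slice_thickness_mm
        )
        original = normalize_to_working(
            read_image(original_path, **geometry), cfg.working_size
        )
        current = normalize_to_working(
            read_image(current_path, **geometry), cfg.working_size
        )
    except (OSError, ValueError) as exc:
        raise PipelineError("input", str(exc)) from exc

    try:
        reg = register(original, current, cfg.registration_config())
    except ValueError as exc:
        raise PipelineError("registration", str(exc)) from exc

    try:
        diff = subtract(original, reg.warped_current)
        sub = colour_code(diff, cfg.change_threshold, cfg.min_area)
    except ValueError as exc:
        raise PipelineError("subtraction", str(exc)) from exc

    try:
        _, _, rois_t1 = _segment_timepoint(original, cfg)
        _, _, rois_t2 = _segment_timepoint(reg.warped_current, cfg)
        if not rois_t1 or not rois_t2:
            raise ValueError("no ROI above min_area at one of the timepoints")
    except ValueError as exc:
        raise PipelineError("segmentation", str(exc)) from exc

    try:
        m1 = _measure_roi(rois_t1[0], original, "t1", cfg)
        m2 = _measure_roi(rois_t2[0], reg.warped_current, "t2", cfg)
        dv, direction = progression(m1.volume, m2.volume)
        feats = temporal_features(rois_t1[0], rois_t2[0])
    except ValueError as exc:
        raise PipelineError("measurement", str(exc)) from exc

    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        import imageio.v3 as iio

        write_image(original.with_pixels(sub.enhanced), outdir / "enhanced.png")
        iio.imwrite(outdir / "overlay.png", sub.overlay)
        write_image(original.with_pixels(diff - diff.min()), outdir / "difference.nii")
        outputs = {
            "enhanced": str(outdir / "enhanced.png"),
            "overlay": str(outdir / "overlay.png"),
            "difference": str(outdir / "difference.nii"),
        }

    t = reg.transform
    report = CaseReport(
        patient_id=patient_id,
        transform={
            "dtx": t.shift.dtx,
            "dty": t.shift.dty,
            "peak_ncc": t.shift.peak_ncc,
            "alpha_deg": math.degrees(t.alpha),
            "r_max": (None if math.isinf(t.r_max) else t.r_max),
            "centre": list(t.centre),
        },
        residual_rmse=reg.residual_rmse,
        rois={
            "t1": [asdict(r) for r in rois_t1[:5]],
            "t2": [asdict(r) for r in rois_t2[:5]],
        },
        measurements={"t1": asdict(m1), "t2": asdict(m2)},
        progression={"dv_cm3": dv, "direction": direction},
        features=feats,
        outputs=outputs,
        config=cfg.to_dict(),
    )
    if write_outputs:
        report.to_json(outdir / "report.json")
    return report


def run_cohort(
    cases: list[tuple[str, str | Path, str | Path]],
    config: PipelineConfig | None = None,
    write_outputs: bool = True,
) -> dict:
    """Run every (patient_id, original, current) case; per-case failures
    are recorded and the cohort continues."""
    if not cases:
        raise ValueError("run_cohort requires at least one case")
    cfg = config or PipelineConfig()
    reports, failures, records = [], {}, []
    for pid, orig, curr in cases:
        try:
            rep = run_pipeline(orig, curr, cfg, patient_id=pid, write_outputs=write_outputs)
            reports.append(rep)
            records.append(
                ProgressionRecord(
                    patient_id=pid,
                    dv=rep.progression["dv_cm3"],
                    direction=rep.progression["direction"],
                    method="auto",
                )
            )
        except PipelineError as exc:
            log.error("case %s failed: %s", pid, exc)
            failures[pid] = str(exc)
    summary = cohort_summary(records) if records else {}
    return {"reports": reports, "failures": failures, "summary": summary}


def validate_translation(
    predicted: list[tuple[float, float]],
    observed: list[tuple[float, float]],
    pixel_spacing_mm: float = 1.0,
) -> dict:
    """Per-axis RMSE (mm) between predicted and observed (dtx, dty)."""
    px = rmse([p[0] for p in predicted], [o[0] for o in observed]) * pixel_spacing_mm
    py = rmse([p[1] for p in predicted], [o[1] for o in observed]) * pixel_spacing_mm
    return {"dtx_rmse_mm": px, "dty_rmse_mm": py, "n": len(predicted)}
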