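"""End-to-end orchestration: stack -> preprocess -> segment -> count.

``run_pipeline`` wires the stages together, logs parameters and counts per
stage, and writes the standard artifact set (cluster CSV, calibration JSON,
dose JSON, size-distribution figure, optional surface meshes) into a run
directory.  Given the same configuration and seed the pipeline is
deterministic and its JSON outputs are byte-identical across runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cell_segmentation as cellseg
from . import np_detection as npdet
from . import preprocess, quantify, stack_io
from .calibration import (
    CalibrationResult,
    SingleSelectionError,
    calibrate,
    select_single_nps,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "default_config"]

log = logging.getLogger("fibsemquant")


def default_config() -> dict:
    """The full configuration tree with package defaults."""
    return {
        "drift": {"enabled": True},
        "view_angle": {"convention": "cos"},  # cos | sin | none
        "wiener": {"window": 5},
        "lowpass": {"sigma": 1.5},
        "cell": {
            "threshold": "otsu",
            "extension_px": 10,
            "smooth_radius_px": 5,
            "notch_tolerance": 0.10,
            "contrast_min_snr": 4.0,
        },
        "np": {
            "roberts_k": 3.0,
            "margin_xy": 5,
            "margin_z": 3,
            "min_voxels": 2,
        },
        "calibration": {
            "nominal_diameter_nm": 74.0,
            "area_tolerance": 0.3,
            "estimator": "empirical",
            "singles": None,  # optional manual cluster-id list
        },
        "histogram": {"bin_width": 10},
        "export_meshes": False,
        "seed": 0,
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Configuration tree; unspecified keys fall back to package defaults."""

    values: dict = field(default_factory=default_config)

    @classmethod
    def from_dict(cls, overrides: dict | None) -> "PipelineConfig":
        return cls(values=_merge(default_config(), overrides or {}))

    def __getitem__(self, key):
        return self.values[key]


@dataclass
class PipelineResult:
    dose: quantify.DoseReport
    calibration: CalibrationResult | None
    clusters: list
    cell_volume: np.ndarray
    flagged_fraction: float
    outdir: Path | None = None


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that caused it."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def _expected_single_area(cfg: dict, geometry: stack_io.VoxelGeometry) -> float:
    d = float(cfg["calibration"]["nominal_diameter_nm"])
    return math.pi * (d / 2.0) ** 2 / geometry.pixel_area


def run_pipeline(
    stack: stack_io.ImageStack,
    config: dict | PipelineConfig | None = None,
    outdir=None,
) -> PipelineResult:
    """Run preprocess -> cell segmentation -> detection -> calibration -> dose.

    Returns the in-memory result; when ``outdir`` is given, also writes
    ``clusters.csv``, ``calibration.json``, ``dose.json``,
    ``size_distribution.png`` (and meshes when enabled) there, regenerating
    every artifact.
    """
    cfg = config.values if isinstance(config, PipelineConfig) else _merge(
        default_config(), config or {}
    )
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(handler)
    try:
        return _run(stack, cfg, outdir)
    finally:
        if outdir is not None:
            log.removeHandler(handler)
            handler.close()


def detect_stack(
    stack: stack_io.ImageStack,
    seg: cellseg.CellSegmentationResult,
    det_params: npdet.NPDetectParams | None = None,
):
    """Normalize, detect and refine nanoparticle clusters for a whole stack.

    Returns ``(aiu_volume, rough_clusters, refined_clusters)``.  Background
    statistics and candidate search use each slice's pre-extension core
    mask, which tracks the true cell boundary.
    """
    det_params = det_params or npdet.NPDetectParams()
    data = stack.as_float()
    aiu = np.zeros_like(data)
    cand = np.zeros(data.shape, dtype=bool)
    for k, mask in enumerate(seg.masks):
        if mask.below_contrast_limit or not mask.mask.any():
            continue
        region = mask.core if mask.core is not None and mask.core.any() else mask.mask
        aiu[k] = npdet.normalize_to_background(data[k], region)
        cand[k] = npdet.detect_np_candidates(aiu[k], region, det_params)
    rough = npdet.cluster_candidates_3d(cand, aiu, det_params.min_voxels)
    refined = npdet.refine_clusters(aiu, rough, det_params, restrict_to=seg.volume)
    return aiu, rough, refined


def _run(stack, cfg, outdir) -> PipelineResult:
    # --- preprocess -------------------------------------------------------
    try:
        if cfg["drift"]["enabled"] and stack.n_slices >= 2:
            trace = preprocess.estimate_drift(stack)
            stack = preprocess.apply_drift_correction(stack, trace)
            log.info(
                "drift: corrected, max |shift| %d px",
                int(np.abs(trace.shifts).max()),
            )
        if cfg["view_angle"]["convention"] != "none" and stack.geometry.view_angle > 0:
            stack = preprocess.correct_view_angle(stack)
            log.info("view angle: corrected to 0 deg")
    except Exception as err:  # noqa: BLE001 - stage labeling
        raise PipelineError("preprocess", err) from err

    # --- cell segmentation ------------------------------------------------
    try:
        cell_params = cellseg.CellSegParams(
            threshold=cfg["cell"]["threshold"],
            extension_px=int(cfg["cell"]["extension_px"]),
            smooth_radius_px=int(cfg["cell"]["smooth_radius_px"]),
            notch_tolerance=float(cfg["cell"]["notch_tolerance"]),
            contrast_min_snr=float(cfg["cell"]["contrast_min_snr"]),
            wiener_window=int(cfg["wiener"]["window"]),
        )
        seg = cellseg.segment_cell_stack(stack, cell_params)
        log.info(
            "cell: %d/%d slices segmented (%.0f%% flagged)",
            sum(not m.below_contrast_limit for m in seg.masks),
            len(seg.masks),
            100 * seg.flagged_fraction,
        )
    except Exception as err:  # noqa: BLE001
        raise PipelineError("cell_segmentation", err) from err

    # --- NP detection -----------------------------------------------------
    try:
        det_params = npdet.NPDetectParams(
            roberts_k=float(cfg["np"]["roberts_k"]),
            lowpass_sigma=float(cfg["lowpass"]["sigma"]),
            margin_xy=int(cfg["np"]["margin_xy"]),
            margin_z=int(cfg["np"]["margin_z"]),
            min_voxels=int(cfg["np"]["min_voxels"]),
        )
        aiu, rough, clusters = detect_stack(stack, seg, det_params)
        log.info("np: %d rough -> %d refined clusters", len(rough), len(clusters))
    except Exception as err:  # noqa: BLE001
        raise PipelineError("np_detection", err) from err

    # --- calibration ------------------------------------------------------
    cal = None
    if clusters:
        try:
            a_expected = _expected_single_area(cfg, stack.geometry)
            manual = cfg["calibration"]["singles"]
            singles = select_single_nps(
                aiu,
                clusters,
                A_expected=a_expected,
                tolerance=float(cfg["calibration"]["area_tolerance"]),
                slice_thickness=stack.geometry.slice_thickness,
                nominal_diameter=float(cfg["calibration"]["nominal_diameter_nm"]),
                manual_ids=manual,
            )
            cal = calibrate(
                aiu,
                singles,
                stack.geometry.slice_thickness,
                estimator=cfg["calibration"]["estimator"],
            )
            log.info(
                "calibration: n_ref=%d, l=%.1f nm, Vs0=%.1f a.i.u., As=%.1f px",
                cal.n_ref,
                cal.l_nm,
                cal.V_s0,
                cal.A_s,
            )
        except SingleSelectionError as err:
            raise PipelineError("calibration", err) from err
        except Exception as err:  # noqa: BLE001
            raise PipelineError("calibration", err) from err

    # --- quantification ---------------------------------------------------
    try:
        if clusters and cal is not None:
            quants = quantify.quantify_clusters(clusters, cal, aiu_volume=aiu)
            dose = quantify.total_dose(
                quants, cal, bin_width=int(cfg["histogram"]["bin_width"])
            )
        else:
            dose = quantify.total_dose([], _placeholder_cal(), 10)
        log.info(
            "dose: N=%d +/- %.0f over %d clusters",
            dose.n_total,
            dose.n_total_sd,
            dose.n_clusters,
        )
    except Exception as err:  # noqa: BLE001
        raise PipelineError("quantify", err) from err

    result = PipelineResult(
        dose=dose,
        calibration=cal,
        clusters=clusters,
        cell_volume=seg.volume,
        flagged_fraction=seg.flagged_fraction,
        outdir=outdir,
    )
    if outdir is not None:
        _write_artifacts(result, stack, cfg, outdir)
    return result


def _placeholder_cal() -> CalibrationResult:
    # used only for the empty-scene dose report (no cluster to count)
    return CalibrationResult(
        l_nm=1.0, l_sd=0.0, V_s=1.0, V_s_sd=0.0, V_s_offset=0.0,
        V_s_offset_sd=0.0, V_s0=1.0, V_s0_sd=0.0, A_s=1.0, A_s_sd=0.0, n_ref=1,
    )


def _write_artifacts(result: PipelineResult, stack, cfg, outdir: Path) -> None:
    result.dose.table.to_csv(outdir / "clusters.csv", index=False)
    result.dose.to_json(outdir / "dose.json")
    if result.calibration is not None:
        result.calibration.to_json(outdir / "calibration.json")
    quantify.plot_size_distribution(result.dose, outdir / "size_distribution.png")
    if cfg.get("export_meshes"):
        labels = result.cell_volume.astype(np.int32)
        for cl in result.clusters:
            labels[tuple(cl.voxels.T)] = cl.id + 1  # cell stays label 1
        try:
            stack_io.export_surface_mesh(labels, stack.geometry, outdir / "surfaces.ply")
        except ValueError:
            log.warning("mesh export skipped: empty label volume")
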