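"""End-to-end driver: preprocess -> segment -> register/refine ->
area series -> polynomial timing -> skeleton velocity.

Deterministic given the configuration and input; optionally writes the
mask stack, the area/fit CSV, the refinement iteration log and a JSON
report (with the full resolved configuration echoed) to an output
directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import AngioSequence, AreaSeries, MaskSequence
from .io import write_masks
from .refinement import SatisfactionCriterion, refine_sequence
from .segmentation import segment_sequence
from .timing import PolyFitResult, compute_area_series, fit_timing
from .velocity import VelocityResult, estimate_mlength

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    velocity: VelocityResult
    fit: PolyFitResult
    area_series: AreaSeries
    masks_initial: MaskSequence
    masks_refined: MaskSequence
    refinement_log: list = field(default_factory=list)
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def report(self) -> dict:
        v = self.velocity
        return {
            "v_mlength_m_per_s": v.v_mlength_m_per_s,
            "m_slope": v.m_slope,
            "t_s": self.fit.t_s,
            "t_max": self.fit.t_max,
            "delta_L_T_mm": v.delta_L_T_mm,
            "delta_T_s": v.delta_T_s,
            "t_s_method": self.fit.t_s_method,
            "t_max_fallback": self.fit.t_max_fallback,
            "rss": self.fit.rss,
            "degree": self.fit.degree,
            "config": self.config.to_dict(),
        }


def run_pipeline(seq: AngioSequence, config: PipelineConfig | None = None,
                 out_dir=None) -> PipelineResult:
    """Run every stage in order on a sequence and estimate the velocity.

    Stage errors are re-raised with the stage name attached. Velocity is
    measured on masks in original (unregistered) geometry; registration
    serves to judge and refine the segmentation.
    """
    config = (config or PipelineConfig()).validate()
    fps = config.fps_override or seq.fps
    spacing = config.spacing_override_mm or seq.pixel_spacing_mm

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    masks_initial, vmaps = stage(
        "segmentation", segment_sequence, seq, th=config.segmentation.th,
        scales_px=config.segmentation.scales_px, return_vesselness=True)

    log: list = []
    if config.refinement.enabled:
        crit = SatisfactionCriterion(
            lower_px=config.refinement.sat_lower_px,
            upper_px=config.refinement.sat_upper_px,
            reference_spacing_mm=config.refinement.reference_spacing_mm)
        masks = stage(
            "refinement", refine_sequence, masks_initial, vmaps, crit,
            max_iter=config.refinement.max_iter, pixel_spacing_mm=spacing,
            settings=config.registration, th_step=config.refinement.th_step,
            d_edge_px=config.refinement.d_edge_px,
            d_center_px=config.refinement.d_center_px, log=log)
    else:
        masks = masks_initial

    series = stage("area", compute_area_series, masks)
    fit = stage("timing", fit_timing, series, degree=config.timing.degree,
                mode=config.timing.t_max_mode, kappa=config.timing.kappa,
                n_base=config.timing.n_base,
                rise_frac=config.timing.rise_frac,
                persist=config.timing.persist)
    vel = stage("velocity", estimate_mlength, masks, fit, fps, spacing,
                mode=config.velocity.mode)

    result = PipelineResult(velocity=vel, fit=fit, area_series=series,
                            masks_initial=masks_initial, masks_refined=masks,
                            refinement_log=log, config=config)
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_masks(result.masks_refined, out_dir / "masks.tif")
    t = result.area_series.frame_index
    pd.DataFrame({
        "frame": t,
        "area_px": result.area_series.area_px,
        "fitted_area_px": result.fit(t.astype(float)),
        "skeleton_length_mm": result.velocity.skeleton_lengths_mm,
    }).to_csv(out_dir / "area_series.csv", index=False)
    with open(out_dir / "refinement_log.txt", "w") as fh:
        for entry in result.refinement_log:
            fh.write(json.dumps(entry) + "\n")
    (out_dir / "report.json").write_text(
        json.dumps(result.report(), indent=2, default=float))
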