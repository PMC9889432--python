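"""End-to-end pipeline: segment → centerline → CPR → length.

A :class:`PipelineConfig` (strict schema: unknown keys rejected) drives
one run; every output directory receives the resolved config and a
manifest with per-stage wall times, so a run is reproducible from its
own artifacts.  With the classical backend the whole pipeline is a pure
function of (volume, config).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from . import __version__
from . import io as dio
from .centerline import CenterlineParams, extract_centerline
from .cpr import generate_cpr, measure_mpd_length
from .grid import Volume3D
from .segmentation import segment_classical


class PipelineConfig(BaseModel):
    """All pipeline parameters; serializable, unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    volume_path: str | None = None
    output_dir: str = "ductcpr_out"
    backend: str = "classical"
    checkpoint_path: str | None = None
    seed: int = 0

    # segmentation
    duct_threshold_hu: float = 60.0
    pancreas_threshold_hu: float = -15.0
    min_component_voxels: int = 20
    opening_radius: int = 1

    # centerline
    epsilon: float = 0.01
    barrier: float = 1.0e6
    smooth_window: int = 9
    resample_step_mm: float = 0.5
    gap_tolerance_mm: float = 5.0
    head_axis: int = 0
    head_sign: int = 1

    # CPR
    lateral_halfwidth_mm: float = 20.0
    sample_spacing_mm: float = 0.5
    frame_mode: str = "straightened"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, volume: Volume3D | None = None) -> dict:
    """Execute all stages on one volume; returns the run manifest.

    ``volume`` may be passed in-memory; otherwise ``config.volume_path``
    is read.  Outputs (masks, centerline JSON, CPR PNG + NIfTI, length
    JSON, manifest, resolved config) land in ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.model_dump_json(indent=2))

    manifest: dict = {"version": __version__, "backend": config.backend, "stages": {}}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["failed_stage"] = name
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {"wall_time_s": round(time.perf_counter() - t0, 4)}
        return result

    if volume is None:
        if config.volume_path is None:
            raise ValueError("either a volume or config.volume_path is required")
        volume = _stage("read", lambda: dio.read_volume(config.volume_path))

    def _segment():
        if config.backend == "classical":
            return segment_classical(
                volume,
                duct_threshold_hu=config.duct_threshold_hu,
                min_component_voxels=config.min_component_voxels,
                pancreas_threshold_hu=config.pancreas_threshold_hu,
                opening_radius=config.opening_radius,
            )
        if config.backend == "unet":
            from .unet import UNetSegmenter, segment_unet

            if config.checkpoint_path is None:
                raise ValueError("unet backend requires checkpoint_path")
            return segment_unet(
                volume,
                UNetSegmenter.load(config.checkpoint_path),
                min_component_voxels=config.min_component_voxels,
                opening_radius=config.opening_radius,
            )
        raise ValueError(f"unknown backend {config.backend!r}")

    seg = _stage("segment", _segment)
    dio.write_mask(seg.pancreas_mask, out / "pancreas_mask.nii.gz")
    dio.write_mask(seg.duct_mask, out / "duct_mask.nii.gz")

    params = CenterlineParams(
        epsilon=config.epsilon,
        barrier=config.barrier,
        smooth_window=config.smooth_window,
        resample_step_mm=config.resample_step_mm,
        gap_tolerance_mm=config.gap_tolerance_mm,
        head_axis=config.head_axis,
        head_sign=config.head_sign,
    )
    path = _stage(
        "centerline", lambda: extract_centerline(seg.pancreas_mask, seg.duct_mask, params)
    )
    dio.write_centerline_json(path, out / "centerline.json")

    cpr = _stage(
        "cpr",
        lambda: generate_cpr(
            volume,
            path,
            lateral_halfwidth_mm=config.lateral_halfwidth_mm,
            sample_spacing_mm=config.sample_spacing_mm,
            frame_mode=config.frame_mode,
        ),
    )
    dio.write_cpr_png(cpr, out / "cpr.png")
    dio.write_cpr_nifti(cpr, out / "cpr.nii.gz")

    length = _stage("measure", lambda: measure_mpd_length(path))
    (out / "length.json").write_text(
        json.dumps(
            {
                "total_mm": length.total_mm,
                "per_segment_mm": length.per_segment_mm,
                "n_segments": length.n_segments,
            },
            indent=2,
        )
    )

    manifest["outputs"] = sorted(p.name for p in out.iterdir())
    manifest["length_mm"] = length.total_mm
    manifest["n_segments"] = length.n_segments
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
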