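"""Pipeline orchestration for the postmortem and in vivo tracks.

External preprocessing (bias-field correction, denoising, rigid/SyN
registration, tissue segmentation, super-resolution synthesis) happens
outside this package; the pipeline consumes their outputs through
declared input slots and wires the internal stages: brain extraction ->
intensity correction -> per-atlas cleaning -> tissue-constrained fusion ->
Voronoi tessellation -> volume aggregation -> optional WMH accounting.
Every run writes intermediates plus a manifest with content hashes, so any
prefix can be re-run reproducibly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import brainseg, fusion, intensity, morphometry, wmh as wmh_mod
from .core import (
    BinaryMask,
    LabelTable,
    LabelVolume,
    ScalarVolume,
    TissueMap,
    write_volume,
)

__all__ = ["PipelineConfig", "PipelineError", "run_postmortem", "run_invivo"]


class PipelineError(RuntimeError):
    """A stage contract violation, annotated with the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    In-memory objects are passed directly; anything not provided disables
    the stages that need it (the pipeline stops after the last runnable
    stage and says so).
    """

    triplet: brainseg.ModelTriplet | None = None
    tissue: TissueMap | None = None
    warped_atlases: list[LabelVolume] | None = None
    label_table: LabelTable | None = None
    wmh_mask: BinaryMask | None = None
    correction: intensity.CorrectionConfig = field(default_factory=intensity.CorrectionConfig)
    fusion_config: fusion.FusionConfig = field(default_factory=fusion.FusionConfig)
    stride: int = 5
    seed: int = 0
    out_dir: Path | None = None


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _maybe_write(obj, name: str, cfg: PipelineConfig, manifest: dict) -> None:
    data = obj.labels if isinstance(obj, LabelVolume) else obj.values
    manifest[name] = _hash(data)
    if cfg.out_dir is not None:
        cfg.out_dir.mkdir(parents=True, exist_ok=True)
        write_volume(obj, cfg.out_dir / f"{name}.nii.gz")


def run_postmortem(t1: ScalarVolume, t2: ScalarVolume,
                   config: PipelineConfig) -> dict:
    """Run the postmortem track as far as the provided inputs allow.

    Returns a result dict with the produced artifacts, the per-stage
    manifest of content hashes, and (when atlases were provided) the final
    parcellation, per-region volumes, and named aggregates.
    """
    manifest: dict[str, str] = {}
    result: dict = {"manifest": manifest}

    if config.triplet is None:
        raise PipelineError("brainseg", "no trained model triplet provided")
    t1.grid.require_compatible(t2.grid)
    logit_sum, raw = brainseg.infer_mask(config.triplet, (t1, t2), stride=config.stride)
    mask = brainseg.clean_mask(raw)
    _maybe_write(logit_sum, "logit_sum", config, manifest)
    _maybe_write(mask, "brain_mask", config, manifest)
    result["mask"] = mask

    corrected = intensity.correct_intensity(t2, mask, config.correction)
    _maybe_write(corrected, "t2_corrected", config, manifest)
    result["t2_corrected"] = corrected

    if config.tissue is None or config.warped_atlases is None or config.label_table is None:
        result["stopped_after"] = "intensity"
        result["message"] = ("tissue map and warped atlases not provided: "
                             "pipeline stopped after intensity correction")
        return result

    table = config.label_table
    cleaned = [
        fusion.clean_warped_parcellation(w, config.tissue, table, config.fusion_config)
        for w in config.warped_atlases
    ]
    fused = fusion.fuse_parcellations(cleaned, config.tissue, table, config.fusion_config)
    _maybe_write(fused.parcellation, "parcellation", config, manifest)
    result["fusion"] = fused

    tessellated, ext_table = fusion.voronoi_tessellate_wm(fused.parcellation, table)
    _maybe_write(tessellated, "parcellation_voronoi", config, manifest)
    result["parcellation"] = tessellated
    result["label_table"] = ext_table

    per_label, aggregates = morphometry.aggregate_volumes(fused.parcellation, table)
    result["volumes"] = per_label
    result["aggregates"] = aggregates

    if config.wmh_mask is not None:
        fractions = wmh_mod.regional_wmh_fractions(config.wmh_mask, tessellated, ext_table)
        swapped, amounts = wmh_mod.corrective_swap(fractions)
        result["wmh_fractions"] = fractions
        result["wmh_swapped"] = swapped
        result["wmh_swap_amounts"] = amounts
    if config.out_dir is not None:
        (config.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def run_invivo(session: list[ScalarVolume], config: PipelineConfig) -> dict:
    """In vivo track: session combination, fusion and aggregation.

    Super-resolution synthesis and registration are upstream; the session
    volumes must already share one grid.  Uses the full (unrestricted)
    atlas set passed in ``config.warped_atlases``.
    """
    if not session:
        raise PipelineError("combine", "empty session")
    manifest: dict[str, str] = {}
    result: dict = {"manifest": manifest}
    combined = intensity.combine_session(session, seed=config.seed)
    _maybe_write(combined, "combined_t1", config, manifest)
    result["combined"] = combined

    if config.tissue is None or config.warped_atlases is None or config.label_table is None:
        result["stopped_after"] = "combine"
        result["message"] = "no atlases/tissue map provided: stopped after session averaging"
        return result
    table = config.label_table
    cleaned = [
        fusion.clean_warped_parcellation(w, config.tissue, table, config.fusion_config)
        for w in config.warped_atlases
    ]
    fused = fusion.fuse_parcellations(cleaned, config.tissue, table, config.fusion_config)
    _maybe_write(fused.parcellation, "parcellation", config, manifest)
    per_label, aggregates = morphometry.aggregate_volumes(fused.parcellation, table)
    result["parcellation"] = fused.parcellation
    result["volumes"] = per_label
    result["aggregates"] = aggregates
    if config.out_dir is not None:
        (config.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
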