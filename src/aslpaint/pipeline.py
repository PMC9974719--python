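"""End-to-end orchestration: phantom -> CBF -> structures -> plans -> report.

`run_pipeline` executes the full analysis on a synthetic acquisition and
writes every artifact (NIfTI volumes and masks, JSON manifests, CSV metric
tables) under one output directory, returning the manifest and the combined
metrics report.  A fixed seed makes the run bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .asl import ASLParameters, compute_cbf, mirror_reference, relative_cbf
from .grid import StructureMask, VolumeGrid
from .io import dump_config_file, write_mask, write_volume
from .phantom import (OAR_NAMES, Phantom, PhantomConfig, generate_phantom,
                      midline_config, unilateral_config)
from .planning import (DoseModelConfig, OARConstraintTable, PLAN_VARIANTS,
                       PlanPrescription, SimulatedPlan, simulate_plan)
from .report import PlanMetricsReport, evaluate_plans
from .structures import (DEFAULT_RCBF_THRESHOLD, MarginPolicy,
                         build_structure_cascade, segment_hyperperfusion)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "default_run_config"]

log = logging.getLogger(__name__)

# Baseline prescription ranges consistent with each anatomical scenario
_SCENARIO_BASELINE_GY = {"unilateral": (55.0, 60.0), "midline": (45.0, 54.0)}


@dataclass
class RunConfig:
    """Complete configuration of one end-to-end run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    asl: ASLParameters = field(default_factory=ASLParameters)
    margins: MarginPolicy = field(default_factory=MarginPolicy)
    rx: PlanPrescription = field(default_factory=PlanPrescription)
    model: DoseModelConfig = field(default_factory=DoseModelConfig)
    constraints: OARConstraintTable = field(default_factory=OARConstraintTable)
    threshold: float = DEFAULT_RCBF_THRESHOLD
    inclusive_threshold: bool = False
    output_dir: str = "aslpaint_run"
    seed: int = 0

    def validate(self) -> None:
        self.phantom.validate()
        if self.threshold <= 0:
            raise ValueError("rCBF threshold must be positive")
        lo, hi = _SCENARIO_BASELINE_GY[self.phantom.scenario]
        if not (lo <= self.rx.baseline_dose_gy <= hi):
            raise ValueError(
                f"baseline prescription {self.rx.baseline_dose_gy} Gy is outside "
                f"the [{lo}, {hi}] Gy range of the '{self.phantom.scenario}' scenario")
        if self.margins.clip_to is not None and self.margins.clip_to != "body":
            raise ValueError("margins.clip_to must be 'body' or None for phantom runs")


def default_run_config(scenario: str = "unilateral", seed: int = 0,
                       **overrides: Any) -> RunConfig:
    """Preset run configurations for the two clinical scenarios.

    "unilateral": hemispheric lesion, 60 Gy baseline, 20% escalation (72 Gy
    boost).  "midline": lesion straddling the midline, 45 Gy baseline, 20%
    escalation (54 Gy boost), rCBF referenced to insula-analog gray matter.
    """
    if scenario == "unilateral":
        cfg = RunConfig(phantom=unilateral_config(seed=seed),
                        rx=PlanPrescription(baseline_dose_gy=60.0,
                                            escalation_fraction=0.20),
                        seed=seed)
    elif scenario == "midline":
        cfg = RunConfig(phantom=midline_config(seed=seed),
                        rx=PlanPrescription(baseline_dose_gy=45.0,
                                            escalation_fraction=0.20),
                        seed=seed)
    else:
        raise ValueError(f"unknown scenario '{scenario}'")
    return replace(cfg, **overrides)


@dataclass
class RunManifest:
    """Inventory of one run: files, checksums, seed, timings, warnings."""

    output_dir: str
    seed: int
    version: str
    config: dict
    files: dict[str, str] = field(default_factory=dict)       # relpath -> sha256
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    scalars: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


class _Recorder:
    def __init__(self, out: Path) -> None:
        self.out = out
        self.manifest_files: dict[str, str] = {}

    def add(self, path: Path) -> None:
        self.manifest_files[str(path.relative_to(self.out))] = _sha256(path)


def run_pipeline(config: RunConfig) -> tuple[RunManifest, PlanMetricsReport]:
    """Run phantom generation, quantification, segmentation, planning and
    evaluation; write all artifacts under ``config.output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = _Recorder(out)
    stage_seconds: dict[str, float] = {}
    warnings: list[str] = []
    t_all = time.perf_counter()

    def stage(name: str):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                stage_seconds[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    log.error("stage '%s' failed: %s", name, exc)
                return False

        return _T()

    phantom_cfg = replace(config.phantom, seed=config.seed)

    with stage("phantom"):
        phantom = generate_phantom(phantom_cfg, asl_params=config.asl)
        pid = f"{phantom_cfg.scenario}_{config.seed}"
        for role, grid in (("asl_control", phantom.asl_control),
                           ("asl_label", phantom.asl_label),
                           ("asl_pd", phantom.asl_pd),
                           ("truth_cbf", phantom.truth_cbf)):
            rec.add(write_volume(grid, out / f"{pid}_{role}.nii.gz"))
        for name, m in {**phantom.tissue_masks, **phantom.structure_masks}.items():
            rec.add(write_mask(m, out / f"{pid}_mask_{name}.nii.gz"))
    log.info("phantom '%s' generated: GTV %.1f cc", pid,
             phantom.structure_masks["GTV"].volume_cc)

    with stage("cbf"):
        cbf = compute_cbf(phantom.asl_control, phantom.asl_label, phantom.asl_pd,
                          config.asl, mask=phantom.tissue_masks["body"])
        rec.add(write_volume(cbf.grid, out / f"{pid}_cbf.nii.gz"))
        if phantom_cfg.scenario == "midline":
            reference = mirror_reference(
                phantom.structure_masks["GTV"], phantom.tissue_masks["gray_matter"],
                midline_reference=phantom.structure_masks["insula_reference"])
        else:
            reference = mirror_reference(phantom.structure_masks["GTV"],
                                         phantom.tissue_masks["gray_matter"])
        rcbf = relative_cbf(cbf, reference)
        rec.add(write_mask(reference, out / f"{pid}_mask_rcbf_reference.nii.gz"))
        rec.add(write_volume(rcbf, out / f"{pid}_rcbf.nii.gz"))
    log.info("CBF quantified; reference mean normalization over %d voxels",
             reference.voxel_count)

    with stage("structures"):
        gtv = phantom.structure_masks["GTV"]
        gtv_asl = segment_hyperperfusion(rcbf, gtv, config.threshold,
                                         inclusive=config.inclusive_threshold)
        if gtv_asl.warning:
            warnings.append(gtv_asl.warning)
        clip = (phantom.tissue_masks["body"]
                if config.margins.clip_to == "body" else None)
        structures, ratio = build_structure_cascade(gtv, gtv_asl, config.margins,
                                                    clip_mask=clip)
        volumes = {}
        for name, m in structures.items():
            rec.add(write_mask(m, out / f"{pid}_mask_{name}.nii.gz"))
            volumes[name] = round(m.volume_cc, 4)
        manifest_path = out / f"{pid}_structures.json"
        manifest_path.write_text(json.dumps(
            {"volumes_cc": volumes, "volume_ratio_ptv_asl_to_ptv": ratio},
            indent=2, sort_keys=True) + "\n")
        rec.add(manifest_path)
    log.info("structure cascade built; PTV-ASL/PTV volume ratio %.2f%%", 100 * ratio)

    oars = {name: phantom.structure_masks[name] for name in OAR_NAMES}
    plans: list[SimulatedPlan] = []
    with stage("plans"):
        for variant in PLAN_VARIANTS:
            plan = simulate_plan(structures, config.rx, config.model, variant,
                                 oar_masks=oars)
            warnings.extend(plan.warnings)
            rec.add(write_volume(plan.dose, out / f"{pid}_dose_{variant}.nii.gz"))
            plans.append(plan)
            log.info("%s: mean(%s) = %.2f Gy after %d iteration(s)", variant,
                     plan.normalization_structure, plan.achieved_mean_gy,
                     plan.iterations)

    with stage("evaluate"):
        report = evaluate_plans(plans, structures, oars, config.constraints,
                                volume_ratio_ptv_asl=ratio)
        warnings.extend(w for w in report.warnings if w not in warnings)
        report.warnings = warnings

        metrics_path = out / f"{pid}_metrics.csv"
        report.structure_metrics.to_csv(metrics_path, index=False,
                                        float_format="%.6f")
        rec.add(metrics_path)
        summary_path = out / f"{pid}_plan_summary.csv"
        report.plan_summary.to_csv(summary_path, index=False, float_format="%.6f")
        rec.add(summary_path)
        changes_path = out / f"{pid}_percent_changes.csv"
        report.changes.to_csv(changes_path, index=False, float_format="%.6f")
        rec.add(changes_path)
        constraints_path = out / f"{pid}_constraints.json"
        constraints_path.write_text(json.dumps(
            {v: r.to_records() for v, r in report.constraints.items()},
            indent=2, sort_keys=True) + "\n")
        rec.add(constraints_path)
        for variant, creport in report.constraints.items():
            log.info("%s: OAR constraints %s", variant,
                     "all met" if creport.all_passed else "VIOLATED")

    manifest = RunManifest(
        output_dir=str(out),
        seed=config.seed,
        version=__version__,
        config=_config_dict(config),
        files=rec.manifest_files,
        stage_seconds=stage_seconds,
        warnings=warnings,
        scalars={
            "volume_ratio_ptv_asl_to_ptv": ratio,
            "gtv_asl_cc": structures["GTV_ASL"].volume_cc,
            "total_seconds": round(time.perf_counter() - t_all, 3),
        },
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    dump_config_file(manifest.config, out / "config.yaml")
    return manifest, report
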