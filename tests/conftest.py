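"""Shared fixtures: phantoms and one full end-to-end run, built once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from aslpaint.asl import compute_cbf, mirror_reference, relative_cbf
from aslpaint.phantom import generate_phantom, unilateral_config
from aslpaint.pipeline import default_run_config
from aslpaint.planning import simulate_plan
from aslpaint.report import evaluate_plans
from aslpaint.structures import build_structure_cascade, segment_hyperperfusion


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default unilateral phantom with noise switched off (exact forward model)."""
    return generate_phantom(unilateral_config(seed=0, noise_sd=0.0))


@pytest.fixture(scope="session")
def default_phantom():
    """Default unilateral phantom with its default acquisition noise."""
    return generate_phantom(unilateral_config(seed=0))


@pytest.fixture(scope="session")
def full_run():
    """The complete default unilateral analysis: phantom through plan metrics.

    Returns a dict with every intermediate object so individual tests can
    probe any stage without re-running the pipeline.
    """
    config = default_run_config("unilateral", seed=0)
    phantom = generate_phantom(config.phantom, asl_params=config.asl)
    cbf = compute_cbf(phantom.asl_control, phantom.asl_label, phantom.asl_pd,
                      config.asl, mask=phantom.tissue_masks["body"])
    reference = mirror_reference(phantom.structure_masks["GTV"],
                                 phantom.tissue_masks["gray_matter"])
    rcbf = relative_cbf(cbf, reference)
    gtv_asl = segment_hyperperfusion(rcbf, phantom.structure_masks["GTV"],
                                     config.threshold)
    structures, ratio = build_structure_cascade(
        phantom.structure_masks["GTV"], gtv_asl, config.margins,
        clip_mask=phantom.tissue_masks["body"])
    from aslpaint.phantom import OAR_NAMES
    oars = {name: phantom.structure_masks[name] for name in OAR_NAMES}
    plans = {v: simulate_plan(structures, config.rx, config.model, v,
                              oar_masks=oars)
             for v in ("plan1", "plan2", "plan3")}
    report = evaluate_plans(list(plans.values()), structures, oars,
                            config.constraints, volume_ratio_ptv_asl=ratio)
    return {
        "config": config, "phantom": phantom, "cbf": cbf, "reference": reference,
        "rcbf": rcbf, "gtv_asl": gtv_asl, "structures": structures,
        "ratio": ratio, "oars": oars, "plans": plans, "report": report,
    }
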