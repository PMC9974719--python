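"""Assembly of per-plan, per-structure metric tables and plan comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dvh import (compute_dvh, conformity_index, coverage, dose_at_absolute_volume,
                  homogeneity_index, structure_doses)
from .grid import StructureMask, VolumeGrid
from .planning import (ConstraintReport, OARConstraintTable, SimulatedPlan,
                       check_constraints)

__all__ = ["PlanMetricsReport", "evaluate_plans", "TARGET_STRUCTURES"]

TARGET_STRUCTURES = ("GTV", "GTV_ASL", "GTV_SUB", "CTV", "PTV", "PTV_ASL", "PTV_SUB")


@dataclass
class PlanMetricsReport:
    """Everything the plan comparison reports.

    structure_metrics: one row per (plan, structure) with D2%/D98%/D50%/
    Dmean/Dmax, D0.1cc for OARs and coverage for targets.
    plan_summary: one row per plan with PTV coverage, CI and HI (computed on
    the PTV, the headline target).
    changes: pairwise percent change (plan_b - plan_a)/plan_a * 100 of every
    metric, recomputed from the absolute values in structure_metrics.
    """

    structure_metrics: pd.DataFrame
    plan_summary: pd.DataFrame
    changes: pd.DataFrame
    constraints: dict[str, ConstraintReport]
    volume_ratio_ptv_asl: float
    warnings: list[str] = field(default_factory=list)

    @property
    def all_constraints_passed(self) -> bool:
        return all(r.all_passed for r in self.constraints.values())


def _percent_changes(metrics: pd.DataFrame,
                     pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    value_cols = [c for c in metrics.columns if c not in ("plan", "structure")]
    wide = metrics.set_index(["plan", "structure"])
    rows = []
    for a, b in pairs:
        da, db = wide.loc[a], wide.loc[b]
        for structure in da.index:
            rec = {"comparison": f"{b} vs {a}", "structure": structure}
            for col in value_cols:
                va, vb = da.loc[structure, col], db.loc[structure, col]
                rec[col] = (vb - va) / va * 100.0 if np.isfinite(va) and va != 0 else np.nan
            rows.append(rec)
    return pd.DataFrame(rows)


def evaluate_plans(plans: Sequence[SimulatedPlan],
                   structures: Mapping[str, StructureMask],
                   oars: Mapping[str, StructureMask],
                   constraint_table: OARConstraintTable = OARConstraintTable(),
                   volume_ratio_ptv_asl: float = float("nan"),
                   bin_width_gy: float = 0.1,
                   ci_reference: str = "prescription") -> PlanMetricsReport:
    """Compute the full metric set for a list of simulated plan variants.

    Target coverage is evaluated at the structure's own prescription: the
    boost dose for the PTV-ASL in boosted plans, the baseline elsewhere.
    CI uses the PTV with the baseline prescription as reference dose
    (``ci_reference="95%"`` switches to 95% of it).
    """
    records: list[dict] = []
    summary: list[dict] = []
    constraints: dict[str, ConstraintReport] = {}
    warnings: list[str] = []

    for plan in plans:
        rx = plan.prescription
        warnings.extend(plan.warnings)
        for name in TARGET_STRUCTURES:
            struct = structures.get(name)
            if struct is None or struct.is_empty:
                continue
            rec = {"plan": plan.variant, "structure": name}
            rec.update(structure_doses(plan.dose, struct, bin_width_gy))
            goal = (rx.boost_dose_gy
                    if plan.boosted and name in ("GTV_ASL", "PTV_ASL")
                    else rx.baseline_dose_gy)
            rec["coverage"] = coverage(plan.dose, struct, goal)
            rec["D0.1cc"] = np.nan
            records.append(rec)
        for name, struct in oars.items():
            if struct.is_empty:
                continue
            rec = {"plan": plan.variant, "structure": name}
            rec.update(structure_doses(plan.dose, struct, bin_width_gy))
            dvh = compute_dvh(plan.dose, struct, bin_width_gy)
            rec["D0.1cc"] = dose_at_absolute_volume(dvh, 0.1)
            rec["coverage"] = np.nan
            records.append(rec)

        ptv = structures["PTV"]
        ref_dose = rx.baseline_dose_gy
        if ci_reference == "95%":
            ref_dose *= 0.95
        ptv_points = structure_doses(plan.dose, ptv, bin_width_gy)
        summary.append({
            "plan": plan.variant,
            "coverage_PTV": coverage(plan.dose, ptv, rx.baseline_dose_gy),
            "CI": conformity_index(plan.dose, ptv, ref_dose),
            "HI": homogeneity_index(ptv_points["D2%"], ptv_points["D98%"],
                                    ptv_points["D50%"]),
            "Dmax_global": float(plan.dose.data.max()),
            "normalization_residual": abs(plan.achieved_mean_gy
                                          - plan.normalization_target_gy)
                                      / plan.normalization_target_gy,
        })
        constraints[plan.variant] = check_constraints(plan.dose, oars, constraint_table)

    metrics = pd.DataFrame(records)
    plan_names = [p.variant for p in plans]
    pairs = [(a, b) for i, a in enumerate(plan_names) for b in plan_names[i + 1:]]
    changes = _percent_changes(metrics, pairs) if len(plan_names) > 1 else pd.DataFrame()
    return PlanMetricsReport(
        structure_metrics=metrics,
        plan_summary=pd.DataFrame(summary),
        changes=changes,
        constraints=constraints,
        volume_ratio_ptv_asl=volume_ratio_ptv_asl,
        warnings=warnings,
    )
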