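"""Plan simulation: normalization, escalation, cap, constraints."""

import dataclasses

import numpy as np
import pytest

from aslpaint.dvh import dose_mean, dose_max, structure_doses
from aslpaint.grid import StructureMask, VolumeGrid
from aslpaint.planning import (DoseModelConfig, OARConstraint, OARConstraintTable,
                               PlanPrescription, check_constraints,
                               local_prescription_map, simulate_plan)


def _sphere_structs(shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0),
                    ptv_r=30.0, boost_r=12.0):
    idx = np.indices(shape).astype(float)
    c = [(s - 1) / 2 for s in shape]
    d2 = sum(((idx[a] - c[a]) * spacing[a]) ** 2 for a in range(3))
    ptv = StructureMask("PTV", d2 <= ptv_r ** 2, spacing)
    boost = StructureMask("PTV_ASL", d2 <= boost_r ** 2, spacing)
    return {"PTV": ptv, "PTV_ASL": boost}


def test_prescription_arithmetic_and_validation():
    rx = PlanPrescription(baseline_dose_gy=60.0, escalation_fraction=0.20)
    assert rx.boost_dose_gy == 72.0
    rx2 = PlanPrescription(baseline_dose_gy=50.0, escalation_fraction=0.10)
    assert rx2.boost_dose_gy == pytest.approx(55.0)
    with pytest.raises(ValueError):
        PlanPrescription(cap_fraction=0.9)
    with pytest.raises(ValueError):
        PlanPrescription(coverage_goal=0.0)


def test_degenerate_kernel_paints_exact_prescription():
    """With a vanishing penumbra, plan 1 is the baseline inside the PTV and
    zero outside, so all PTV dose points equal the baseline."""
    structs = _sphere_structs()
    rx = PlanPrescription(baseline_dose_gy=60.0)
    model = DoseModelConfig(penumbra_sigma_mm=0.0)
    plan = simulate_plan(structs, rx, model, "plan1")
    inside = plan.dose.data[structs["PTV"].mask]
    outside = plan.dose.data[~structs["PTV"].mask]
    np.testing.assert_allclose(inside, 60.0, rtol=1e-12)
    np.testing.assert_allclose(outside, 0.0, atol=1e-12)
    pts = structure_doses(plan.dose, structs["PTV"])
    assert pts["D2%"] == pts["D98%"] == pytest.approx(60.0, abs=0.1)
    assert pts["Dmean"] == pytest.approx(60.0)


def test_normalization_contract_all_variants():
    structs = _sphere_structs()
    rx = PlanPrescription(baseline_dose_gy=60.0, escalation_fraction=0.20)
    for variant, struct, target in (("plan1", "PTV", 60.0),
                                    ("plan2", "PTV_ASL", 72.0),
                                    ("plan3", "PTV_ASL", 72.0)):
        plan = simulate_plan(structs, rx, DoseModelConfig(), variant)
        mean = dose_mean(plan.dose, structs[struct])
        assert abs(mean - target) / target < 0.005
        assert np.all(plan.dose.data >= 0.0)


def test_boost_escalates_mean_dose_by_escalation_fraction():
    """Dmean over PTV-ASL in plan 2 exceeds plan 1 by the escalation
    fraction (the normalization contract) within 1%."""
    structs = _sphere_structs()
    rx = PlanPrescription(baseline_dose_gy=60.0, escalation_fraction=0.20)
    p1 = simulate_plan(structs, rx, DoseModelConfig(), "plan1")
    p2 = simulate_plan(structs, rx, DoseModelConfig(), "plan2")
    ratio = (dose_mean(p2.dose, structs["PTV_ASL"])
             / dose_mean(p1.dose, structs["PTV_ASL"]))
    assert ratio == pytest.approx(1.20, rel=0.01)


def test_mean_boost_dose_monotone_in_escalation():
    structs = _sphere_structs()
    means = []
    for esc in (0.05, 0.10, 0.15, 0.20):
        rx = PlanPrescription(baseline_dose_gy=60.0, escalation_fraction=esc)
        plan = simulate_plan(structs, rx, DoseModelConfig(), "plan2")
        means.append(dose_mean(plan.dose, structs["PTV_ASL"]))
    assert np.all(np.diff(means) >= 0)


def test_cap_contract_and_uncapped_plan3():
    structs = _sphere_structs()
    rx = PlanPrescription(baseline_dose_gy=60.0, escalation_fraction=0.20)
    p2 = simulate_plan(structs, rx, DoseModelConfig(), "plan2")
    p3 = simulate_plan(structs, rx, DoseModelConfig(), "plan3")
    local = local_prescription_map(structs, rx, "plan2")
    assert np.all(p2.dose.data <= rx.cap_fraction * local + 1e-6)
    # removing the cap can only raise the maximum
    assert p3.dose.data.max() >= p2.dose.data.max() - 1e-9
    # and the cold end of each target barely moves
    for name in ("PTV", "PTV_ASL"):
        d2 = structure_doses(p2.dose, structs[name])["D98%"]
        d3 = structure_doses(p3.dose, structs[name])["D98%"]
        assert abs(d2 - d3) < 1.0


def test_dose_falls_off_far_from_target():
    structs = _sphere_structs()
    rx = PlanPrescription(baseline_dose_gy=60.0)
    model = DoseModelConfig()
    plan = simulate_plan(structs, rx, model, "plan1")
    # distance from PTV surface in mm on the grid
    from scipy import ndimage
    dist = ndimage.distance_transform_edt(~structs["PTV"].mask,
                                          sampling=structs["PTV"].spacing)
    far = dist >= model.flash_mm + 5 * model.penumbra_sigma_mm
    assert far.any()
    assert plan.dose.data[far].max() < 0.01 * rx.baseline_dose_gy


def test_empty_boost_falls_back_to_conventional_plan():
    structs = _sphere_structs()
    structs["PTV_ASL"] = structs["PTV_ASL"].with_mask(
        np.zeros(structs["PTV"].shape, bool))
    rx = PlanPrescription(baseline_dose_gy=60.0, escalation_fraction=0.20)
    p1 = simulate_plan(structs, rx, DoseModelConfig(), "plan1")
    p2 = simulate_plan(structs, rx, DoseModelConfig(), "plan2")
    assert p2.warnings and "fall" in p2.warnings[0]
    assert not p2.boosted
    np.testing.assert_allclose(p2.dose.data, p1.dose.data, rtol=1e-12)


def test_check_constraints_uniform_doses():
    spacing = (2.0, 2.0, 2.0)
    shape = (12, 12, 12)
    stem = np.zeros(shape, bool)
    stem[2:10, 2:10, 2:10] = True  # 4.1 cc
    structs = {"brain_stem": StructureMask("brain_stem", stem, spacing)}
    table = OARConstraintTable(rows=(OARConstraint("brain_stem", "D0.1cc", 54.0),))
    ok = check_constraints(VolumeGrid(np.full(shape, 50.0), spacing), structs, table)
    assert ok.all_passed and ok.rows[0].observed_gy == pytest.approx(50.0, abs=0.1)
    bad = check_constraints(VolumeGrid(np.full(shape, 55.0), spacing), structs, table)
    assert not bad.all_passed
    row = bad.rows[0]
    assert row.observed_gy == pytest.approx(55.0, abs=0.1) and row.limit_gy == 54.0
    with pytest.raises(ValueError, match="optic_chiasm"):
        check_constraints(VolumeGrid(np.full(shape, 10.0), spacing), structs,
                          OARConstraintTable(rows=(
                              OARConstraint("optic_chiasm", "Dmax", 55.0),)))


def test_constraint_table_rejects_duplicates():
    with pytest.raises(ValueError, match="duplicate"):
        OARConstraintTable(rows=(OARConstraint("a", "Dmax", 10.0),
                                 OARConstraint("a", "Dmax", 20.0)))
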