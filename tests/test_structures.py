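"""Target-volume derivation: thresholding, mask algebra, margin expansion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aslpaint.asl import compute_cbf, mirror_reference, relative_cbf
from aslpaint.grid import GeometryError, StructureMask, VolumeGrid
from aslpaint.structures import (MarginPolicy, build_structure_cascade,
                                 expand_margin, segment_hyperperfusion, subtract)


def _mask(arr, spacing=(2.0, 2.0, 2.0), name="m"):
    return StructureMask(name, np.asarray(arr, dtype=bool), spacing)


def _sphere_mask(shape, spacing, center_vox, radius_mm, name="s"):
    idx = np.indices(shape).astype(float)
    d2 = sum(((idx[a] - center_vox[a]) * spacing[a]) ** 2 for a in range(3))
    return StructureMask(name, d2 <= radius_mm ** 2, spacing)


# ---------------------------------------------------------------- thresholding

def test_toy_threshold_enumeration():
    """3x3x1 toy: exactly the 4 ratios strictly above 1.4 are selected."""
    ratios = np.array([1.2, 1.39, 1.4, 1.41, 2.0, 0.9, 1.5, 1.0, 1.45]
                      ).reshape(3, 3, 1)
    rel = VolumeGrid(ratios, (2, 2, 2))
    gtv = _mask(np.ones((3, 3, 1)), name="GTV")
    out = segment_hyperperfusion(rel, gtv, 1.4)
    assert out.voxel_count == 4
    assert set(np.round(ratios[out.mask], 2)) == {1.41, 2.0, 1.5, 1.45}
    # the value 1.4 itself is excluded (strict inequality) ...
    assert not out.mask.ravel()[2]
    # ... unless the inclusive flag is set
    out_inc = segment_hyperperfusion(rel, gtv, 1.4, inclusive=True)
    assert out_inc.voxel_count == 5


def test_empty_selection_warns_not_errors():
    rel = VolumeGrid(np.full((2, 2, 2), 1.0), (2, 2, 2))
    gtv = _mask(np.ones((2, 2, 2)), name="GTV")
    out = segment_hyperperfusion(rel, gtv, 1.4)
    assert out.is_empty
    assert out.warning is not None and "fall back" in out.warning


def test_noiseless_phantom_recovers_ground_truth_core(noiseless_phantom):
    """On the noiseless phantom the thresholded GTV-ASL is exactly the
    constructed hyper-perfused core (edema rCBF < 1.4 < core rCBF)."""
    ph = noiseless_phantom
    cbf = compute_cbf(ph.asl_control, ph.asl_label, ph.asl_pd,
                      mask=ph.tissue_masks["body"])
    ref = mirror_reference(ph.structure_masks["GTV"], ph.tissue_masks["gray_matter"])
    rel = relative_cbf(cbf, ref)
    out = segment_hyperperfusion(rel, ph.structure_masks["GTV"], 1.4)
    np.testing.assert_array_equal(out.mask,
                                  ph.structure_masks["hyperperfused_core"].mask)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.5, 3.0), st.floats(0.0, 1.0))
def test_raising_threshold_never_grows_selection(seed, t_low, delta):
    rng = np.random.default_rng(seed)
    rel = VolumeGrid(rng.uniform(0, 3, (5, 5, 5)), (2, 2, 2))
    gtv = _mask(rng.random((5, 5, 5)) > 0.3, name="GTV")
    low = segment_hyperperfusion(rel, gtv, t_low)
    high = segment_hyperperfusion(rel, gtv, t_low + delta)
    assert np.all(low.mask[high.mask])  # high-threshold set is a subset


# ------------------------------------------------------------------- subtract

def test_subtract_identities():
    rng = np.random.default_rng(3)
    a = _mask(rng.random((4, 4, 4)) > 0.5, name="a")
    b = _mask(rng.random((4, 4, 4)) > 0.5, name="b")
    empty = _mask(np.zeros((4, 4, 4)), name="empty")
    assert subtract(a, a).is_empty
    np.testing.assert_array_equal(subtract(a, empty).mask, a.mask)
    once = subtract(a, b)
    np.testing.assert_array_equal(subtract(once, b).mask, once.mask)
    # volume identity |a \ b| = |a| - |a & b|
    assert once.voxel_count == a.voxel_count - int((a.mask & b.mask).sum())
    disjoint = _mask(~a.mask, name="d")
    np.testing.assert_array_equal(subtract(a, disjoint).mask, a.mask)
    with pytest.raises(GeometryError):
        subtract(a, _mask(np.zeros((4, 4, 5)), name="other"))


# -------------------------------------------------------------- margin growth

def test_zero_margin_is_identity():
    m = _mask(np.pad(np.ones((2, 2, 2)), 2), name="m")
    np.testing.assert_array_equal(expand_margin(m, 0.0).mask, m.mask)


def test_single_voxel_3mm_margin_on_2mm_grid_gives_19_voxels():
    """Offsets with 2*sqrt(i^2+j^2+k^2) <= 3: the centre, 6 faces, 12 edges."""
    arr = np.zeros((5, 5, 5), bool)
    arr[2, 2, 2] = True
    out = expand_margin(_mask(arr), 3.0)
    assert out.voxel_count == 19


def test_sphere_expansion_volume_ratio():
    """r=10 mm sphere grown by 10 mm on a 1 mm grid: volume ratio close to
    (20/10)^3 = 8."""
    m = _sphere_mask((45, 45, 45), (1, 1, 1), (22, 22, 22), 10.0)
    out = expand_margin(m, 10.0)
    assert out.voxel_count / m.voxel_count == pytest.approx(8.0, rel=0.03)


def _brute_force_expand(mask, spacing, margin):
    src = np.argwhere(mask) * np.asarray(spacing)
    all_idx = np.argwhere(np.ones(mask.shape, bool)) * np.asarray(spacing)
    d2 = ((all_idx[:, None, :] - src[None, :, :]) ** 2).sum(-1).min(1)
    return (d2 <= margin ** 2 + 1e-12).reshape(mask.shape)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1),
       st.tuples(st.sampled_from([1.0, 1.5, 2.0]), st.sampled_from([1.0, 2.0, 3.0]),
                 st.sampled_from([1.0, 2.0, 2.5])),
       st.floats(0.5, 8.0))
def test_expansion_matches_all_pairs_distance_oracle(seed, spacing, margin):
    """On small grids the EDT expansion equals a brute-force all-pairs
    physical-distance computation, including anisotropic spacing."""
    rng = np.random.default_rng(seed)
    arr = rng.random((7, 6, 8)) > 0.9
    if not arr.any():
        arr[3, 3, 3] = True
    out = expand_margin(StructureMask("m", arr, spacing), margin)
    np.testing.assert_array_equal(out.mask,
                                  _brute_force_expand(arr, spacing, margin))


def test_expansion_monotone_in_margin_and_superset():
    m = _sphere_mask((30, 30, 30), (2, 2, 2), (15, 15, 15), 8.0)
    prev = m
    for margin in (0.0, 2.0, 5.0, 9.0):
        cur = expand_margin(m, margin)
        assert np.all(cur.mask[m.mask])          # superset of the input
        assert np.all(cur.mask[prev.mask])       # monotone in the margin
        prev = cur
    with pytest.raises(ValueError, match="empty"):
        expand_margin(m.with_mask(np.zeros(m.shape, bool)), 2.0)


# -------------------------------------------------------------------- cascade

def test_cascade_nested_spheres_volume_ratio():
    """Concentric GTV r=25 / core r=12 on a 1 mm grid: PTV-ASL/PTV volume
    ratio close to ((12+3)/(25+10+5))^3 = 5.27%."""
    shape, spacing, c = (96, 96, 96), (1.0, 1.0, 1.0), (48, 48, 48)
    gtv = _sphere_mask(shape, spacing, c, 25.0, "GTV")
    core = _sphere_mask(shape, spacing, c, 12.0, "GTV_ASL")
    structures, ratio = build_structure_cascade(gtv, core, MarginPolicy())
    assert ratio == pytest.approx((15.0 / 40.0) ** 3, rel=0.05)
    # nesting chain and containment invariants
    assert np.all(structures["CTV"].mask[structures["GTV"].mask])
    assert np.all(structures["PTV"].mask[structures["CTV"].mask])
    assert np.all(structures["PTV"].mask[structures["PTV_ASL"].mask])
    # subtraction bookkeeping
    assert (structures["PTV_SUB"].voxel_count
            == structures["PTV"].voxel_count - structures["PTV_ASL"].voxel_count)


def test_cascade_with_empty_boost_volume():
    gtv = _sphere_mask((40, 40, 40), (2, 2, 2), (20, 20, 20), 12.0, "GTV")
    empty = gtv.with_mask(np.zeros(gtv.shape, bool), name="GTV_ASL")
    structures, ratio = build_structure_cascade(gtv, empty, MarginPolicy())
    assert ratio == 0.0
    np.testing.assert_array_equal(structures["PTV_SUB"].mask,
                                  structures["PTV"].mask)
    np.testing.assert_array_equal(structures["GTV_SUB"].mask, gtv.mask)


def test_cascade_rejects_boost_outside_gtv():
    gtv = _sphere_mask((30, 30, 30), (2, 2, 2), (15, 15, 15), 8.0, "GTV")
    rogue = _sphere_mask((30, 30, 30), (2, 2, 2), (5, 5, 5), 4.0, "GTV_ASL")
    with pytest.raises(ValueError, match="contained"):
        build_structure_cascade(gtv, rogue, MarginPolicy())


def test_cascade_clipping_restricts_to_body(full_run):
    structures = full_run["structures"]
    body = full_run["phantom"].tissue_masks["body"]
    for name in ("CTV", "PTV", "PTV_ASL"):
        assert np.all(body.mask[structures[name].mask])
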