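"""Cumulative dose-volume histograms and plan-quality metrics.

Conventions
-----------
* Voxel counting: a voxel is wholly in or out of a structure; no sub-voxel
  partial-volume weighting.  Absolute metrics of very small structures
  (e.g. the lens) are therefore spacing-sensitive.
* Dx% is read off the cumulative DVH with linear interpolation between bin
  edges, ties broken toward the higher dose, so the reported value lies
  within one bin width above the exact order statistic.
* Dmax is the maximum in-mask voxel dose (no near-max smoothing).

Plan-level indices follow the standard definitions

    CI = (V_t,ref)^2 / (V_t * V_ref)        conformity index
    HI = (D2% - D98%) / D50%                homogeneity index

where V_t is the target volume, V_ref the volume of all voxels receiving at
least the reference dose and V_t,ref their intersection.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np

from .grid import StructureMask, VolumeGrid

__all__ = ["DVHCurve", "compute_dvh", "dose_at_volume", "dose_at_absolute_volume",
           "conformity_index", "homogeneity_index", "coverage",
           "dose_mean", "dose_max", "structure_doses"]


@dataclass
class DVHCurve:
    """Cumulative DVH sampled at uniform dose-bin edges."""

    dose_edges: np.ndarray          # Gy, uniform spacing, starts at 0
    cum_volume_fraction: np.ndarray  # fraction of volume receiving >= edge dose
    structure_volume_cc: float
    structure_name: str = ""
    min_dose_gy: float = 0.0
    max_dose_gy: float = float("inf")

    @property
    def bin_width_gy(self) -> float:
        return float(self.dose_edges[1] - self.dose_edges[0])


def _in_mask_doses(dose: VolumeGrid, structure: StructureMask) -> np.ndarray:
    dose.require_same_geometry(structure)
    if structure.is_empty:
        raise ValueError(f"structure '{structure.name}' is empty")
    return dose.data[structure.mask]


def compute_dvh(dose: VolumeGrid, structure: StructureMask,
                bin_width_gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH of a structure: fraction of volume receiving >= each edge."""
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be positive")
    doses = np.sort(_in_mask_doses(dose, structure))
    dmax = float(doses[-1])
    n_edges = int(np.floor(max(dmax, 0.0) / bin_width_gy)) + 2
    edges = np.arange(n_edges) * bin_width_gy
    # voxels with dose >= edge, via binary search on the sorted doses
    idx = np.searchsorted(doses, edges, side="left")
    cum = (doses.size - idx) / doses.size
    return DVHCurve(edges, cum, structure.volume_cc, structure.name,
                    min_dose_gy=float(doses[0]), max_dose_gy=dmax)


def dose_at_volume(dvh: DVHCurve, volume_fraction: float) -> float:
    """Dx: minimum dose received by the hottest ``volume_fraction`` of volume.

    D2% = dose_at_volume(dvh, 0.02), etc.  Linear interpolation between the
    cumulative bin edges; ties toward the higher dose.  The result is clipped
    to the actual in-mask dose range so that D98% <= D50% <= D2% <= Dmax
    holds despite within-bin interpolation.
    """
    if not (0.0 < volume_fraction <= 1.0):
        raise ValueError(f"volume_fraction must be in (0, 1], got {volume_fraction}")
    c = dvh.cum_volume_fraction
    e = dvh.dose_edges
    # last edge whose cumulative fraction still reaches volume_fraction
    ge = np.flatnonzero(c >= volume_fraction)
    i = int(ge[-1])
    if i == len(e) - 1:
        d = float(e[i])
    else:
        c0, c1 = c[i], c[i + 1]
        if c0 == c1:
            d = float(e[i + 1])
        else:
            frac = (c0 - volume_fraction) / (c0 - c1)
            d = float(e[i] + frac * (e[i + 1] - e[i]))
    return float(min(max(d, dvh.min_dose_gy), dvh.max_dose_gy))


def dose_at_absolute_volume(dvh: DVHCurve, cc: float = 0.1) -> float:
    """DVcc: minimum dose received by the hottest ``cc`` cm^3 (e.g. D0.1cc).

    If the structure is smaller than ``cc`` the minimum structure dose is
    returned and a warning is emitted.
    """
    if cc <= 0:
        raise ValueError("cc must be positive")
    if cc >= dvh.structure_volume_cc:
        _warnings.warn(
            f"structure '{dvh.structure_name}' volume "
            f"{dvh.structure_volume_cc:.3g} cc is smaller than the requested "
            f"{cc} cc; returning the minimum structure dose", stacklevel=2)
        return dose_at_volume(dvh, 1.0)
    return dose_at_volume(dvh, cc / dvh.structure_volume_cc)


def dose_mean(dose: VolumeGrid, structure: StructureMask) -> float:
    return float(_in_mask_doses(dose, structure).mean())


def dose_max(dose: VolumeGrid, structure: StructureMask) -> float:
    return float(_in_mask_doses(dose, structure).max())


def coverage(dose: VolumeGrid, target: StructureMask, prescription_gy: float) -> float:
    """Fraction of target voxels receiving at least the prescription dose."""
    doses = _in_mask_doses(dose, target)
    return float(np.count_nonzero(doses >= prescription_gy) / doses.size)


def conformity_index(dose: VolumeGrid, target: StructureMask,
                     reference_dose_gy: float) -> float:
    """CI = (V_t,ref)^2 / (V_t * V_ref); 0 when nothing reaches the reference."""
    dose.require_same_geometry(target)
    if target.is_empty:
        raise ValueError(f"target '{target.name}' is empty")
    if reference_dose_gy <= 0:
        raise ValueError("reference_dose_gy must be positive")
    ref_region = dose.data >= reference_dose_gy
    v_ref = int(ref_region.sum())
    if v_ref == 0:
        return 0.0
    v_t = target.voxel_count
    v_t_ref = int((ref_region & target.mask).sum())
    return float(v_t_ref ** 2 / (v_t * v_ref))


def homogeneity_index(d2: float, d98: float, d50: float) -> float:
    """HI = (D2% - D98%) / D50%; 0 for a perfectly uniform target dose."""
    if d50 <= 0:
        raise ValueError("D50% must be positive")
    if d2 < d98:
        raise ValueError(f"D2% ({d2}) must be >= D98% ({d98})")
    return (d2 - d98) / d50


def structure_doses(dose: VolumeGrid, structure: StructureMask,
                    bin_width_gy: float = 0.1,
                    d_cc: float | None = None) -> dict[str, float]:
    """All per-structure dose points in one pass: D2/D98/D50/Dmean/Dmax (+DVcc)."""
    dvh = compute_dvh(dose, structure, bin_width_gy)
    out = {
        "D2%": dose_at_volume(dvh, 0.02),
        "D98%": dose_at_volume(dvh, 0.98),
        "D50%": dose_at_volume(dvh, 0.50),
        "Dmean": dose_mean(dose, structure),
        "Dmax": dose_max(dose, structure),
    }
    if d_cc is not None:
        out[f"D{d_cc:g}cc"] = dose_at_absolute_volume(dvh, d_cc)
    return out
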