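"""Target-volume derivation: rCBF thresholding, mask algebra, margins.

The clinical cascade reproduced here is

    GTV-ASL = { voxels in GTV with rCBF > threshold }   (threshold 1.4)
    GTV-SUB = GTV \\ GTV-ASL
    CTV     = GTV  + 10 mm isotropic margin
    PTV     = CTV  +  5 mm
    PTV-ASL = GTV-ASL + 3 mm
    PTV-SUB = PTV \\ PTV-ASL

Margins are physical Euclidean distances (mm) honouring anisotropic voxel
spacing, computed voxel-centre to voxel-centre with an exact Euclidean
distance transform.  CTV/PTV are clipped to the body mask by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

from .grid import StructureMask, VolumeGrid

__all__ = ["MarginPolicy", "segment_hyperperfusion", "subtract", "expand_margin",
           "build_structure_cascade", "DEFAULT_RCBF_THRESHOLD"]

DEFAULT_RCBF_THRESHOLD = 1.4


@dataclass(frozen=True)
class MarginPolicy:
    """Margin sizes (mm) of the target-volume cascade."""

    ctv_margin_mm: float = 10.0
    ptv_margin_mm: float = 5.0
    ptv_asl_margin_mm: float = 3.0
    clip_to: str | None = "body"  # structure name used to clip expansions

    def __post_init__(self) -> None:
        for name in ("ctv_margin_mm", "ptv_margin_mm", "ptv_asl_margin_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def segment_hyperperfusion(relative_cbf: VolumeGrid, gtv: StructureMask,
                           threshold: float = DEFAULT_RCBF_THRESHOLD,
                           inclusive: bool = False) -> StructureMask:
    """Hyper-perfusion sub-volume (GTV-ASL) by rCBF thresholding.

    Selects GTV voxels with relative CBF strictly greater than ``threshold``
    (``inclusive=True`` switches to >= for sensitivity checks).  The result
    is always contained in the GTV.  An empty result is not an error: it is
    returned with a ``warning`` set, and downstream planning falls back to a
    conventional (un-boosted) plan.
    """
    relative_cbf.require_same_geometry(gtv)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if inclusive:
        sel = relative_cbf.data >= threshold
    else:
        sel = relative_cbf.data > threshold
    out = sel & gtv.mask
    warning = None
    if not out.any():
        warning = (f"no GTV voxel exceeds rCBF threshold {threshold}; "
                   "dose-painting plans will fall back to the conventional plan")
    return gtv.with_mask(out, name="GTV_ASL", warning=warning)


def subtract(a: StructureMask, b: StructureMask, name: str | None = None) -> StructureMask:
    """Set difference a \\ b of two masks sharing one geometry."""
    a.require_same_geometry(b)
    return a.with_mask(a.mask & ~b.mask, name=name or f"{a.name}-sub")


def expand_margin(mask: StructureMask, margin_mm: float,
                  clip_to: StructureMask | None = None,
                  name: str | None = None) -> StructureMask:
    """Isotropic physical-distance expansion of a binary mask.

    Returns the voxels whose Euclidean distance (in mm, voxel centre to voxel
    centre, using the voxel spacing per axis) to the nearest mask voxel is
    <= ``margin_mm``.  Always a superset of ``mask`` (before clipping).
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    if mask.is_empty:
        raise ValueError(f"cannot expand empty mask '{mask.name}'")
    if margin_mm == 0:
        out = mask.mask.copy()
    else:
        # EDT of the complement: distance from every voxel to the nearest
        # in-mask voxel centre (0 inside the mask).
        dist = ndimage.distance_transform_edt(~mask.mask, sampling=mask.spacing)
        out = dist <= margin_mm
    if clip_to is not None:
        mask.require_same_geometry(clip_to)
        out &= clip_to.mask
    return mask.with_mask(out, name=name or f"{mask.name}+{margin_mm:g}mm")


def build_structure_cascade(gtv: StructureMask, gtv_asl: StructureMask,
                            policy: MarginPolicy = MarginPolicy(),
                            clip_mask: StructureMask | None = None,
                            ) -> tuple[dict[str, StructureMask], float]:
    """Derive CTV, PTV, PTV-ASL, the SUB volumes, and the PTV-ASL/PTV ratio.

    ``gtv_asl`` must be contained in ``gtv``; it may be empty, in which case
    PTV-ASL is empty, PTV-SUB equals the PTV and the volume ratio is 0.
    Returns (structure set including the inputs, volume ratio PTV-ASL/PTV).
    """
    gtv.require_same_geometry(gtv_asl)
    if (gtv_asl.mask & ~gtv.mask).any():
        raise ValueError("GTV-ASL must be contained in the GTV")

    ctv = expand_margin(gtv, policy.ctv_margin_mm, clip_to=clip_mask, name="CTV")
    ptv = expand_margin(ctv, policy.ptv_margin_mm, clip_to=clip_mask, name="PTV")
    if gtv_asl.is_empty:
        ptv_asl = gtv_asl.with_mask(np.zeros(gtv.shape, dtype=bool), name="PTV_ASL",
                                    warning=gtv_asl.warning)
    else:
        ptv_asl = expand_margin(gtv_asl, policy.ptv_asl_margin_mm,
                                clip_to=clip_mask, name="PTV_ASL")
    gtv_sub = subtract(gtv, gtv_asl, name="GTV_SUB")
    ptv_sub = subtract(ptv, ptv_asl, name="PTV_SUB")

    ratio = ptv_asl.volume_cc / ptv.volume_cc if ptv.voxel_count else 0.0
    structures = {
        "GTV": gtv, "GTV_ASL": gtv_asl, "GTV_SUB": gtv_sub,
        "CTV": ctv, "PTV": ptv, "PTV_ASL": ptv_asl, "PTV_SUB": ptv_sub,
    }
    return structures, ratio
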