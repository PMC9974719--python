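"""Single-delay pseudo-continuous ASL quantification.

CBF is obtained voxelwise from the control/label difference signal with the
standard single-compartment closed form

    CBF = 6000 * lambda * (SI_control - SI_label) * exp(PLD / T1b)
          -----------------------------------------------------------
          2 * alpha * T1b * SI_PD * (1 - exp(-tau / T1b))        [ml/100 g/min]

where lambda is the brain/blood partition coefficient (ml/g), T1b the
longitudinal relaxation time of arterial blood (s), alpha the labeling
efficiency, tau the label duration (s), PLD the post-labeling delay (s) and
SI_PD a proton-density-weighted calibration image.  The factor 6000 converts
ml/g/s to the customary ml/100 g/min.

Relative CBF (rCBF) divides the CBF map by the mean CBF of a reference
region: the gray matter mirrored across the mid-sagittal plane for a
unilateral lesion, or a configured insula-analog gray-matter region when the
lesion straddles the midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GeometryError, StructureMask, VolumeGrid

__all__ = [
    "ASLParameters",
    "CBFMap",
    "cbf_scale_factor",
    "compute_cbf",
    "relative_cbf",
    "mirror_reference",
]

# Plausibility window for T1 of blood after unit conversion; catches ms-for-s
# mistakes (1650 "s" is rejected, 1650 ms -> 1.65 s is accepted).
_T1_BLOOD_RANGE_S = (0.5, 3.0)


@dataclass(frozen=True)
class ASLParameters:
    """Quantification constants.  All times are stored in seconds."""

    lambda_partition: float = 0.9   # ml/g
    t1_blood: float = 1.65          # s
    alpha: float = 0.85             # labeling efficiency
    tau: float = 1.5                # label duration, s
    pld: float = 2.025              # post-labeling delay, s

    def __post_init__(self) -> None:
        for name in ("lambda_partition", "t1_blood", "alpha", "tau", "pld"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ASL parameter {name} must be positive")
        if self.alpha > 1:
            raise ValueError(f"labeling efficiency alpha must be <= 1, got {self.alpha}")
        lo, hi = _T1_BLOOD_RANGE_S
        if not (lo <= self.t1_blood <= hi):
            raise ValueError(
                f"t1_blood = {self.t1_blood} s is outside the plausible range "
                f"[{lo}, {hi}] s; milliseconds passed as seconds? "
                "Use ASLParameters.from_ms for millisecond inputs."
            )

    @classmethod
    def from_ms(cls, lambda_partition: float = 0.9, t1_blood_ms: float = 1650.0,
                alpha: float = 0.85, tau_ms: float = 1500.0,
                pld_ms: float = 2025.0) -> "ASLParameters":
        """Construct from millisecond timings as printed in acquisition protocols."""
        return cls(lambda_partition, t1_blood_ms / 1000.0, alpha,
                   tau_ms / 1000.0, pld_ms / 1000.0)


@dataclass
class CBFMap:
    """A quantified CBF volume plus the parameters that produced it."""

    grid: VolumeGrid
    params: ASLParameters
    n_masked_pd: int = 0  # voxels excluded because SI_PD was effectively zero

    @property
    def data(self) -> np.ndarray:
        return self.grid.data


def cbf_scale_factor(params: ASLParameters) -> float:
    """The scalar multiplying (SI_control - SI_label)/SI_PD in the closed form.

    For the default parameters this evaluates to about 1.10003e4, so a
    difference-to-PD ratio of 0.005 maps to 55 ml/100 g/min.
    """
    t1b = params.t1_blood
    num = 6000.0 * params.lambda_partition * np.exp(params.pld / t1b)
    den = 2.0 * params.alpha * t1b * (1.0 - np.exp(-params.tau / t1b))
    return float(num / den)


def compute_cbf(control: VolumeGrid, label: VolumeGrid, pd: VolumeGrid,
                params: ASLParameters = ASLParameters(),
                mask: StructureMask | None = None,
                clamp_negative: bool = False) -> CBFMap:
    """Quantify CBF (ml/100 g/min) from control/label/PD signal volumes.

    Parameters
    ----------
    control, label, pd
        Signal volumes sharing one geometry.  ``pd`` must be strictly
        positive on the evaluation mask.
    mask
        Optional evaluation region (e.g. the head).  Outside it CBF is 0.
    clamp_negative
        If True, noise-driven negative CBF voxels are clamped at zero.
        Off by default because clamping biases region means.

    Notes
    -----
    Inside the mask, voxels whose PD signal falls below 1e-9 of the in-mask
    median are excluded (set to 0 and counted in ``n_masked_pd``) rather than
    propagated as infinities.
    """
    control.require_same_geometry(label, pd)
    if mask is not None:
        control.require_same_geometry(mask)
        sel = mask.mask
    else:
        sel = np.ones(control.shape, dtype=bool)

    pd_in = pd.data[sel]
    n_nonpos = int(np.count_nonzero(pd_in <= 0))
    if n_nonpos:
        raise ValueError(
            f"SI_PD must be positive on the evaluation mask: {n_nonpos} "
            "non-positive voxel(s) found"
        )
    median_pd = float(np.median(pd_in))
    degenerate = sel & (pd.data < 1e-9 * median_pd)
    usable = sel & ~degenerate

    cbf = np.zeros(control.shape, dtype=np.float64)
    scale = cbf_scale_factor(params)
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf[usable] = scale * (control.data[usable] - label.data[usable]) / pd.data[usable]
    if clamp_negative:
        np.maximum(cbf, 0.0, out=cbf)
    return CBFMap(control.like(cbf), params, n_masked_pd=int(degenerate.sum()))


def relative_cbf(cbf: CBFMap | VolumeGrid, reference: StructureMask) -> VolumeGrid:
    """CBF map divided by the scalar mean CBF over the reference region."""
    grid = cbf.grid if isinstance(cbf, CBFMap) else cbf
    grid.require_same_geometry(reference)
    if reference.is_empty:
        raise ValueError(f"reference region '{reference.name}' is empty")
    ref_mean = float(grid.data[reference.mask].mean())
    if ref_mean <= 0:
        raise ValueError(
            f"mean CBF over reference '{reference.name}' is {ref_mean:.3g}; "
            "cannot normalize"
        )
    return grid.like(grid.data / ref_mean)


def mirror_reference(mask: StructureMask, tissue: StructureMask,
                     midline_reference: StructureMask | None = None) -> StructureMask:
    """Reference region for rCBF normalization.

    Reflects ``mask`` (typically the GTV) across the grid's central x-plane
    (the declared mid-sagittal plane) and intersects with the gray-matter
    ``tissue`` mask.  For midline lesions pass ``midline_reference`` (the
    insula-analog gray-matter region), which is returned intersected with
    gray matter instead.
    """
    mask.require_same_geometry(tissue)
    if midline_reference is not None:
        mask.require_same_geometry(midline_reference)
        out = midline_reference.mask & tissue.mask
        if not out.any():
            raise ValueError("configured midline reference does not intersect gray matter")
        return tissue.with_mask(out, name="rCBF_reference")

    reflected = mask.mask[::-1, :, :]
    out = reflected & tissue.mask
    if not out.any():
        raise ValueError(
            "mirrored reference does not intersect gray matter; for midline "
            "lesions supply the insula-analog midline_reference instead"
        )
    return tissue.with_mask(out, name="rCBF_reference")
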