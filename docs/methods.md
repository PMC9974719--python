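# Methods

This note records the models, defaults and numerical conventions behind
`aslpaint`, the choices made where the design was genuinely open, and what
the synthetic phantom does and does not establish about real data.

## ASL quantification model

CBF is computed voxelwise with the standard single-compartment,
single-delay pCASL closed form (see README for the formula). All times are
handled internally in **seconds**; the public `ASLParameters.from_ms`
constructor accepts protocol-style millisecond values and converts. A
plausibility guard rejects `t1_blood` outside [0.5, 3] s after conversion,
so passing 1650 (ms) where seconds are expected fails loudly instead of
silently mis-scaling CBF by a factor of 1000. For the default parameters
the scalar multiplying (SI_control − SI_label)/SI_PD is 1.10003 × 10⁴, so a
difference-to-PD ratio of 0.005 maps to 55 ml/100 g/min.

Numerical safeguards: voxels whose PD signal is below 10⁻⁹ of the in-mask
median are excluded (counted in `CBFMap.n_masked_pd`) rather than producing
infinities; noise-driven negative CBF voxels are **retained** by default
(an optional clamp exists) because clamping at zero biases region means,
and region means drive the rCBF normalization.

The quantification assumes one already-averaged control/label pair (the
acquisition's repeated pairs and excitations are emulated by a single noise
level, below). Multi-delay kinetic modeling, motion and partial-volume
correction are out of scope: the phantom generates signals that are already
"corrected" in this sense.

## Relative CBF reference

For a unilateral lesion the reference is the gray-matter mask intersected
with the lesion mask reflected across the grid's **central x-plane** (the
declared mid-sagittal plane; registration-based asymmetry correction of
real data is out of scope). For midline lesions, where mirroring would hit
the lesion itself, a configured insula-analog gray-matter region is used
instead. rCBF is the CBF map divided by the scalar mean CBF over this
reference.

## Hyper-perfusion segmentation

GTV-ASL = {GTV voxels with rCBF **strictly greater than** 1.4}; a config
flag switches to ≥ for sensitivity checks. The selection is intersected
with the GTV (hyper-perfusion in this setting lies within the edema, and
containment makes GTV-SUB = GTV \ GTV-ASL well defined). No connected-
component or minimum-volume filtering is applied by default — the clinical
workflow's manual radiologist editing is not reproducible — and the raw
(unsmoothed) rCBF map is thresholded. An empty selection is a warning, not
an error: the dose-painting plans then degenerate to the conventional plan,
mirroring the clinical fallback.

## Margins and mask algebra

`expand_margin` selects voxels whose Euclidean distance — in physical mm
using the per-axis voxel spacing, **voxel centre to voxel centre** — to the
nearest in-mask voxel is ≤ the margin. This convention is exact against a
brute-force all-pairs oracle (tested on small grids) and is the convention
behind all reported volumes. CTV/PTV/PTV-ASL expansions are clipped to the
body contour by default (external-beam convention; configurable off).
Structure volume is voxel count × voxel volume, reported in cc.

## Dose model

The commercial optimizer and dose engine are replaced by an explicit,
deliberately simple stand-in — this is the largest modeling gap in the
package, and every dosimetric number must be read accordingly. The model:

1. paint the baseline prescription on the PTV expanded by a fluence
   "flash" margin (default 3 × penumbra σ = 15 mm), plus the boost
   increment on the flash-expanded PTV-ASL for plans 2–3;
2. convolve with an isotropic Gaussian penumbra kernel
   (σ = 5 mm default);
3. fixed-point iterate (≤ 20 steps) three simultaneous rules stated
   without an ordering in the planning protocol:
   * mean dose over the normalization structure equals its prescription
     (PTV at baseline for plan 1, PTV-ASL at the boost for plans 2–3),
     to within 0.5%;
   * at least 95% of PTV voxels receive the baseline prescription
     (the coverage goal); the scale may exceed exact mean normalization
     by at most 90% of the 0.5% tolerance to achieve this;
   * plans 1–2 only: no voxel exceeds 110% of the **structure-local**
     prescription (the boost dose inside PTV-ASL, the baseline
     elsewhere), applied as a hard clip. Whether the cap inside the boost
     region should reference the boost or the global baseline is
     ambiguous in the protocol wording; `cap_mode="baseline"` selects
     the stricter global reading.

   If the three rules cannot be reconciled the plan raises
   `PlanInfeasibleError` naming the conflict.

The flash margin is the model's analog of an optimizer extending fluence
beyond the target edge so the target reaches its prescription; without it,
mean normalization would leave the entire penumbra band below prescription
and no coverage goal could be met. Dose and all metrics are computed on
the phantom grid (2 mm isotropic by default); a trilinear resampling helper
to a coarser dose grid exists but is not used by the default pipeline,
because the structure masks live on the phantom grid. Beam geometry, field
angles, fluence optimization and radiobiological indices have no analog in
this kernel model.

## DVH and plan metrics

DVHs use voxel counting (no sub-voxel partial-volume weighting — absolute
metrics of very small structures such as the lens are therefore
spacing-sensitive), uniform 0.1 Gy bins by default, and cumulative
fractions "volume receiving ≥ dose". Dx% interpolates linearly between
cumulative bin edges with ties broken toward the higher dose, then clips
to the actual in-mask dose range so D98% ≤ D50% ≤ D2% ≤ Dmax always holds;
the result agrees with a direct order-statistic computation within one bin
width, and all dose-point comparisons carry a one-bin tolerance. Dmax is
the maximum in-mask voxel dose, matching the intent of Dmax-type OAR
limits. D0.1cc of a structure smaller than 0.1 cc returns the minimum
structure dose with a warning. CI uses the baseline prescription as
reference dose by default (95% of it configurable). HI is computed per
target from its own D2/D98/D50; the plan-level headline HI is the PTV's.

## Synthetic phantom

The phantom emulates the *statistical structure* the analysis assumes, not
MR physics. Geometry (all analytic spheres/capsules rasterized by
voxel-centre inclusion, so volumes have closed-form oracles): body sphere
r = 94 mm; brain r = 80 mm with a white-matter core r = 55 mm and a
gray-matter shell; GTV sphere r = 25 mm at (−48, 15, 8) mm (left
hemisphere) containing an **eccentric** hyper-perfused core r = 12 mm
offset 8 mm toward the midline — hyper-perfused cores are typically not
concentric with the edema, and the eccentricity brings the boost volume
near enough to the PTV surface that dose painting visibly bulges the
prescription isodose (lower CI), as seen clinically; brain stem, eyeballs,
lenses, optic nerves and chiasm as carved, pairwise-disjoint primitives at
anatomical positions. Default grid 128 × 128 × 96 at 2 mm isotropic (keeps
the lenses resolvable), origin at the grid centre so the mid-sagittal
mirror plane is exact.

Ground-truth CBF levels (ml/100 g/min): gray matter 60, white matter 20,
edema 40, core 120 — plausible physiological placeholders chosen so the
core/reference ratio (2.0) clearly exceeds the 1.4 threshold while edema
(0.67) clearly does not. Signals: per-compartment PD levels (brain 1000,
rest-of-head 600), control = PD, and label = control − ΔM with
ΔM = CBF · PD / scale — the exact inverse of the quantification closed
form, so noiseless quantification reproduces the truth map to < 10⁻⁶.
Acquisition noise is a single knob: independent Gaussian noise
(σ = 0.5 signal units by default) added to control and label, i.e. a
per-voxel CBF σ of about 8 ml/100 g/min, representative of a well-averaged
3D-ASL series; the repeated-pair averaging of a real protocol is folded
into this one number. One seeded `numpy` Generator drives all draws; equal
seeds give bit-identical phantoms.

Two presets mirror the two anatomical scenarios: `unilateral`
(hemispheric lesion, 60 Gy baseline, 20% escalation → 72 Gy boost) and
`midline` (lesion straddling the mid-sagittal plane, insula rCBF
reference, 45 Gy baseline, 20% escalation → 54 Gy boost, within the
45–54 Gy / 50–60 Gy ranges used for midline disease).

**What passing tests show — and don't.** The phantom validates the
*machinery*: exact model inversion, margin geometry, metric definitions,
normalization/cap/coverage logic, determinism. It does not validate
performance on real data: there is no registration error, no asymmetric
anatomy, no partial-volume mixing at tissue borders, no spatially
correlated noise, and the dose model is not an optimizer. Cohort-level
dosimetric magnitudes from patient studies (e.g. boost-induced CI loss of
~19%, PTV-ASL/PTV ratios of ~23%) depend on patient geometry and TPS
behaviour and are reproduced here only in *direction* (boosted PTV-ASL
dose points, CI down, HI up), not magnitude; the phantom's PTV-ASL/PTV
ratio is ~5% by its nested-sphere geometry.

## Problem sizes and determinism

The default end-to-end run (1.57 M voxels, three plans) takes a few
seconds on one CPU; the test suite builds phantoms once per session and
reuses them. Property tests use seeded/derandomized generators. CSV
reports are written with fixed float formatting, so a fixed seed
reproduces every artifact byte for byte.

## Known limitations

* The Gaussian-penumbra dose model reproduces the prescription,
  normalization, cap and constraint *rules*, not optimizer trade-offs;
  its PTV dose is far more homogeneous than a real plan's (plan 1 HI
  ~0.003 vs ~0.07 clinically), which inflates relative HI changes.
* Voxel-counting DVHs make small-structure metrics (lens Dmax)
  discretization-sensitive.
* The mid-sagittal plane is assumed to be the grid's central x-plane;
  real-data lateralization requires prior spatial normalization.
* No DICOM/DICOM-RT; NIfTI, YAML/JSON and CSV only.
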