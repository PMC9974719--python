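"""Build the clinical target-volume cascade with physical-distance margins.

GTV + 10 mm -> CTV, CTV + 5 mm -> PTV, GTV-ASL + 3 mm -> PTV-ASL, and the
set differences GTV-SUB / PTV-SUB.  Margins are Euclidean distances in mm
(honouring voxel spacing); expansions are clipped to the body contour.
"""

from aslpaint import (build_structure_cascade, compute_cbf, generate_phantom,
                      mirror_reference, relative_cbf, segment_hyperperfusion,
                      unilateral_config, MarginPolicy)

phantom = generate_phantom(unilateral_config(seed=17))
cbf = compute_cbf(phantom.asl_control, phantom.asl_label, phantom.asl_pd,
                  mask=phantom.tissue_masks["body"])
rcbf = relative_cbf(cbf, mirror_reference(phantom.structure_masks["GTV"],
                                          phantom.tissue_masks["gray_matter"]))
gtv_asl = segment_hyperperfusion(rcbf, phantom.structure_masks["GTV"])

structures, ratio = build_structure_cascade(
    phantom.structure_masks["GTV"], gtv_asl, MarginPolicy(),
    clip_mask=phantom.tissue_masks["body"])

for name in ("GTV", "GTV_ASL", "GTV_SUB", "CTV", "PTV", "PTV_ASL", "PTV_SUB"):
    print(f"{name:8s} {structures[name].volume_cc:9.2f} cc")
print(f"\nPTV-ASL / PTV volume ratio: {100 * ratio:.2f}%")
# The boost target is a small fraction of the planning volume: only the
# hyper-perfused sub-volume is escalated, not the whole edema-based PTV.
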