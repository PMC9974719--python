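"""Segment the hyper-perfused sub-volume (GTV-ASL) by rCBF thresholding.

The relative CBF map is the CBF map divided by the mean CBF of gray matter
mirrored across the mid-sagittal plane (the contralateral reference for a
unilateral lesion).  GTV voxels with rCBF > 1.4 form the GTV-ASL — the
dose-painting boost target.  On the phantom the recovered GTV-ASL can be
compared against the constructed hyper-perfused core.
"""

import numpy as np

from aslpaint import (compute_cbf, generate_phantom, mirror_reference,
                      relative_cbf, segment_hyperperfusion, unilateral_config)

phantom = generate_phantom(unilateral_config(seed=17))
cbf = compute_cbf(phantom.asl_control, phantom.asl_label, phantom.asl_pd,
                  mask=phantom.tissue_masks["body"])
reference = mirror_reference(phantom.structure_masks["GTV"],
                             phantom.tissue_masks["gray_matter"])
rcbf = relative_cbf(cbf, reference)
gtv_asl = segment_hyperperfusion(rcbf, phantom.structure_masks["GTV"], 1.4)

core = phantom.structure_masks["hyperperfused_core"]
overlap = (gtv_asl.mask & core.mask).sum()
dice = 2 * overlap / (gtv_asl.voxel_count + core.voxel_count)
print(f"reference region:      {reference.voxel_count} voxels of mirrored gray matter")
print(f"GTV-ASL volume:        {gtv_asl.volume_cc:.2f} cc "
      f"(ground-truth core {core.volume_cc:.2f} cc)")
print(f"Dice vs truth core:    {dice:.4f}")
# Dice is close to 1: with realistic noise the rCBF > 1.4 rule recovers the
# hyper-perfused core almost voxel-for-voxel (exactly, if noise is zero).
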