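"""Generate a synthetic brain phantom and quantify its CBF map.

Builds the default unilateral-lesion phantom (spherical head/brain, a
T2-Flair-like edema region with an eccentric hyper-perfused core, cranial
OARs) and recovers CBF from the simulated control/label/PD signals with the
single-delay closed form.  The printed errors show that quantification
inverts the forward signal model up to the injected acquisition noise.
"""

import numpy as np

from aslpaint import compute_cbf, generate_phantom, unilateral_config

phantom = generate_phantom(unilateral_config(seed=17))
cbf = compute_cbf(phantom.asl_control, phantom.asl_label, phantom.asl_pd,
                  mask=phantom.tissue_masks["body"])

brain = phantom.tissue_masks["brain"].mask
err = cbf.data[brain] - phantom.truth_cbf.data[brain]
print(f"GTV volume:            {phantom.structure_masks['GTV'].volume_cc:.2f} cc")
print(f"core volume:           {phantom.structure_masks['hyperperfused_core'].volume_cc:.2f} cc")
print(f"per-voxel CBF error:   mean {err.mean():+.3f}, sd {err.std():.2f} ml/100g/min")
gm = phantom.tissue_masks["gray_matter"].mask
print(f"gray-matter CBF:       {cbf.data[gm].mean():.2f} (truth 60) ml/100g/min")
# The mean error is tiny because noise averages out over regions; the
# per-voxel sd reflects the configured acquisition noise (about 8 ml/100g/min).
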