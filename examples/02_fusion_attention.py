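"""Voxel-wise cross-modality attention fusion on one phantom.

The four MRI sequences are embedded by one shared convolution; a per-voxel
MLP scores them and a softmax yields modality weights summing to 1 at every
voxel.  The fused volume is the weighted (convex) combination, and the
attention field itself can be exported as four NIfTI maps.
"""

import numpy as np

from gliomark.cmaf import CMAF, CmafConfig, export_attention_maps
from gliomark.nn import no_grad
from gliomark.phantom import PhantomSpec, generate_phantom

case = generate_phantom(PhantomSpec(volume_shape=(32, 32, 32), core_radius=5,
                                    rim_thickness=2, halo_width=3, seed=7))
cmaf = CMAF(CmafConfig(channels=8), np.random.default_rng(0)).eval()

with no_grad():
    fused, attention = cmaf(case.images.images[None])

print(f"fused feature volume: {fused.shape}  (C'=8 channels)")
a = attention.data[0]
print(f"attention field: {a.shape}; per-voxel sums in "
      f"[{a.sum(axis=0).min():.6f}, {a.sum(axis=0).max():.6f}] (always 1)")
for i, m in enumerate(("t1", "t1ce", "t2", "flair")):
    print(f"  mean weight {m:5s} = {a[i].mean():.4f}")

maps = export_attention_maps(attention.data, directory="scratch/attention_maps")
print("wrote one NIfTI attention map per modality to scratch/attention_maps/")
print("(an untrained module spreads weight ~uniformly; training concentrates "
      "it on the sequence that carries each region's contrast)")
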