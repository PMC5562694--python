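"""Generate one synthetic pre/post-treatment lesion pair and inspect it.

The phantom emulates a contrast-enhancing bladder lesion attached to the
bladder wall, imaged at two time points on an anisotropic CT grid.
"""

import numpy as np

from bladresp import PhantomParams, generate_case

params = PhantomParams(seed=7)        # partial responder: 10 mm -> 6 mm
case = generate_case(params)

full = case.true_mask_pre.to_full_grid(case.pre.shape)
print(f"grid {case.pre.shape}, spacing {case.pre.spacing_mm} mm")
print(f"pre-treatment lesion: {case.true_mask_pre.n_voxels} voxels "
      f"({case.true_mask_pre.volume_mm3(params.spacing_mm):.0f} mm^3)")
print(f"mean lesion intensity {case.pre.intensities[full].mean():.1f} "
      f"(lumen {params.lumen_level}, requested contrast {params.lesion_contrast})")
print(f"post-treatment lesion: {case.true_mask_post.n_voxels} voxels")
print(f"response label: {case.label.value}")
# The lesion mean sits ~lesion_contrast above the lumen level; the post
# lesion is smaller because this case only partially responded.
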