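"""Extract both radiomics banks and the pre->post percent change.

The SL bank (91 features) describes the segmented 3D lesion; the ROI bank
(38 features) describes a 32x32 paired ROI; RF-SL classifies the percent
change of the SL bank between time points.
"""

from bladresp import PhantomParams, generate_case
from bladresp.radiomics import (extract_roi_features, extract_sl_features,
                                percent_change)
from bladresp.roipair import extract_rois, pair_rois

case = generate_case(PhantomParams(seed=2))
fv_pre = extract_sl_features(case.pre, case.true_mask_pre)
fv_post = extract_sl_features(case.post, case.true_mask_post)
pct = percent_change(fv_pre, fv_post)

print(f"SL bank: {len(fv_pre)} features")
for name in ("volume_mm3", "gl_mean", "contrast", "rls3d_q8_lre"):
    print(f"  {name}: pre {fv_pre[name]:.2f}, post {fv_post[name]:.2f}, "
          f"change {pct[name]:+.1f}%")

pairs = pair_rois(extract_rois(case.pre, case.true_mask_pre),
                  extract_rois(case.post, case.true_mask_post),
                  case.label, max_pairs=4, seed=0)
roi_fv = extract_roi_features(pairs[0].patch)
print(f"ROI bank: {len(roi_fv)} features; mean {roi_fv['mean']:.1f}, "
      f"skewness {roi_fv['skewness']:.2f}")
# A shrinking lesion shows a large negative volume change; a vanished
# lesion would drive most SL features to -100%.
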