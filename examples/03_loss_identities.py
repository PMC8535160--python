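"""The local-integral losses in closed form on hand-built density maps.

A density map is ideal when every object square integrates to 1 and the
background is exactly 0; both supervised losses vanish there. The weakly
supervised loss compares truncated patch counts to ternary indicators.
"""

import numpy as np

from lirnet import (
    PointAnnotationSet,
    WSLLossParams,
    build_supervision_mask,
    fsl_loss_l1,
    fsl_loss_l2tanh,
    patch_labels_from_points,
    truncate_count,
    wsl_total_loss,
)

pts = PointAnnotationSet("demo", np.array([(4.0, 4.0), (11.0, 12.0)]), (16, 16))
mask = build_supervision_mask(pts, 3)

ideal = np.zeros((16, 16))
for r0, r1, c0, c1 in mask.object_rects:
    ideal[r0:r1, c0:c1] = 1.0 / 9.0

print("ideal map:    l1 loss =", fsl_loss_l1(ideal, mask),
      " l2/tanh loss =", fsl_loss_l2tanh(ideal, mask))
zero = np.zeros((16, 16))
print("all-zero map: l1 loss =", fsl_loss_l1(zero, mask),
      "(one unit per missed nucleus)")
print("              l2/tanh loss =", fsl_loss_l2tanh(zero, mask),
      "(the object-term weight lambda)")

params = WSLLossParams(gamma=1e-4)
print("\ntruncated counts: T(1.5) =", truncate_count(1.5, params),
      " T(2) =", truncate_count(2.0, params),
      " T(10) =", truncate_count(10.0, params))
# past a count of 2 the truncation keeps only a tiny slope gamma, so dense
# patches cannot dominate the gradient

labels = patch_labels_from_points(pts, large_size=8, small_size=4, seed=0)
print("weak loss on the ideal map:", wsl_total_loss(ideal, labels, params, form="l1"))
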