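"""Localization and matching on a hand-built density map (no training).

Shows the post-processing contract on its own: the map integral fixes the
number of detections, greedy maxima extraction with circular erasure places
them, and golden-region matching scores them against the true centroids.
"""

import numpy as np

from lirnet import (
    GaussianGTParams,
    LocalizationParams,
    MatchParams,
    PointAnnotationSet,
    compute_metrics,
    count_from_density,
    gaussian_density_map,
    localize,
    match_detections,
)

true_points = PointAnnotationSet(
    "demo", np.array([(10.0, 12.0), (30.0, 40.0), (50.0, 20.0), (52.0, 55.0)]), (64, 64)
)
density = gaussian_density_map(true_points, GaussianGTParams(sigma=2.0))
print(f"density integral {density.total:.3f} -> count {count_from_density(density)}")

detections = localize(density, LocalizationParams(nms_radius=5))
print("detections (row, col, score):")
for r, c, s in detections.detections:
    print(f"  ({r:2d}, {c:2d})  {s:.4f}")

match = match_detections(detections, true_points, MatchParams(golden_radius=6.0))
m = compute_metrics(match)
print(f"TP {m.tp}  FP {m.fp}  FN {m.fn}  ->  precision {m.precision:.3f} "
      f"recall {m.recall:.3f} F1 {m.f1:.3f}")
print(f"distance quartiles (median, Q1, Q3) = ({m.median:.3f}, {m.q1:.3f}, {m.q3:.3f}) px")
# On an exact synthetic density the four maxima land on the four nuclei:
# everything is a true positive at distance < 1 px.
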