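"""Physical-scale normalization and point-to-point error metrics.

Hand radiographs have no stored physical resolution, so every image gets a
mm-per-pixel scale from the convention that the wrist pair (landmarks 2
and 6) spans 50 mm.
"""

import numpy as np

from landloc import LandmarkSet, normalization_constant, point_error, summarize

coords = np.zeros((6, 2))
coords[1] = (60.0, 200.0)   # landmark 2
coords[5] = (110.0, 200.0)  # landmark 6, 50 px away -> 1 mm per px
lms = LandmarkSet(coords)

s = normalization_constant(lms)
print(f"scale: {s:.3f} mm/px  (wrist separation of 50 px means 1 mm per pixel)")

pe = point_error(pred=(100.0, 100.0), target=(103.0, 104.0), scale=s)
print(f"point error of a (3,4) px miss: {pe:.2f} mm")

summary = summarize([0.4, 0.9, 1.7, 2.4, 4.2, 11.0], radii_mm=[2, 4, 10])
print(f"median {summary.median_mm:.2f} mm, mean {summary.mean_mm:.2f} mm, "
      f"SD {summary.sd_mm:.2f} mm")
print("outliers:", {f">{r:g}mm": c for r, c in summary.outlier_counts.items()})
print("counts use a strict '>' comparison: an error exactly at the radius "
      "is not an outlier.")
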