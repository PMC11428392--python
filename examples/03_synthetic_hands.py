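"""Generate a synthetic hand dataset with 37 landmark annotations.

The generator emulates the geometry of hand radiographs: five finger
chains (the thumb one joint short), a wrist pair at nominally 50 px, ridge
rendering for bones, global affine variation, and per-landmark jitter.
"""

import numpy as np

from landloc import normalization_constant
from landloc.synthetic import SyntheticConfig, make_dataset

ds = make_dataset(SyntheticConfig(n_images=12, frame=(128, 128), seed=0))
print(f"{len(ds)} images of shape {ds.images[0].shape}, "
      f"{len(ds.landmarks[0])} landmarks each")

scales = [normalization_constant(lms) for lms in ds.landmarks]
print(f"mm-per-pixel scales: mean {np.mean(scales):.2f}, "
      f"spread {np.std(scales):.3f} (the affine scale jitter)")

train, test = ds.folds[0]
print(f"fold 0: {len(train)} training / {len(test)} test images; "
      "three folds partition the dataset")
vis = np.mean([lms.visible.mean() for lms in ds.landmarks])
print(f"fraction of in-frame landmarks: {vis:.3f}")
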