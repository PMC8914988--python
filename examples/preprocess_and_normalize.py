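"""Run the preprocessing chain and verify the body-size normalization.

Each 20x10 frame is upsampled x3 (bilinear), smoothed with a 5x5 Gaussian,
rescaled by the subject's anthropometric ratios, and rigidly shifted per
wearing round onto an 84x42 canvas.  The example prints the shape chain
and the between-subject contact-area variance before and after
normalization.
"""

import numpy as np
import pandas as pd

from smartsleeve.features import contact_area
from smartsleeve.preprocessing import preprocess_dataset
from smartsleeve.synthetic import SyntheticConfig, generate_dataset

frames, anthro = generate_dataset(SyntheticConfig(n_subjects=6, n_rounds=3, seed=7))
samples = preprocess_dataset(frames, anthro)

s = samples[0]
print(f"shape chain: {frames[0].values.shape} -> {s.smoothed_image.shape} "
      f"-> {s.normalized_image.shape}")

df = pd.DataFrame({
    "subject": [s.subject_id for s in samples],
    "activity": [s.activity for s in samples],
    "pre": [contact_area(s.smoothed_image) for s in samples],
    "post": [contact_area(s.normalized_image) for s in samples],
})
var = {
    col: df.groupby("activity", sort=False)
    .apply(lambda g: g.groupby("subject")[col].mean().var(), include_groups=False)
    .mean()
    for col in ("pre", "post")
}
print(f"between-subject contact-area variance: "
      f"pre={var['pre']:.0f}  post={var['post']:.0f}  "
      f"ratio={var['post'] / var['pre']:.2f}")
print("\nA ratio below 1 means the anthropometric rescale + per-round shift "
      "removed part of the body-size differences between subjects.")
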