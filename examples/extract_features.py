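"""Extract the 100-feature descriptor from a pressure image.

Shows the three feature families on one synthetic sample: statistical
(order/dispersion of pixel values), geometric (centroid, bounding box,
Hu moments, coverages, contours) and symmetry (per-side mass around the
center of mass / centroid), and the 200-feature sample vector.
"""

from smartsleeve import features as ft
from smartsleeve.preprocessing import preprocess_dataset
from smartsleeve.synthetic import SyntheticConfig, generate_dataset

frames, anthro = generate_dataset(SyntheticConfig(n_subjects=2, n_rounds=1, seed=3))
samples = preprocess_dataset(frames, anthro)
sample = next(s for s in samples if s.activity == "think")

vec = ft.extract_image(sample.smoothed_image)
named = dict(zip(ft.FEATURE_NAMES, vec))
print("statistical (Feat1-8):")
print(f"  max={named['Feat1']:.0f}  median={named['Feat2']:.1f}  "
      f"sum={named['Feat3']:.0f}  mean={named['Feat5']:.1f}  entropy={named['Feat8']:.2f}")
print("geometric:")
print(f"  centroid=({named['Feat9']:.1f}, {named['Feat10']:.1f}) px (x, y)   "
      f"area={named['Feat21']:.0f} px   contours={named['Feat37']:.0f}")
print(f"  Hu1={named['Feat22']:.4f} (translation/rotation/scale invariant)")
print("symmetry:")
print(f"  pressure left/right of center of mass: "
      f"{named['Feat55']:.0f} / {named['Feat56']:.0f}  (ratio {named['Feat58']:.2f})")

full = ft.extract_sample(sample)
print(f"\nsample vector: {len(full)} features "
      f"(100 from the smoothed image + 100 from the normalized image)")
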