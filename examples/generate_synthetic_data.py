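"""Generate a small annotated synthetic rodent-gait dataset.

Renders side-view frames of an articulated rat walking on a treadmill-style
belt, with all nine landmarks annotated at sub-pixel precision, and prints
basic dataset statistics.
"""

import numpy as np

import ratpose as rp

ds = rp.generate_dataset(25, "scratch/example_dataset", seed=42)

dist = [r.landmarks.nose_eye_distance() for r in ds.records]
print(f"generated {len(ds)} annotated frames in scratch/example_dataset/")
print(f"image size: {ds.records[0].width} x {ds.records[0].height}")
print(f"nose-eye distance: {np.mean(dist):.1f} +/- {np.std(dist):.1f} px")
print("  (this distance is the denominator of the normalised accuracy metric;")
print("   a prediction counts as correct within 0.1 of it, i.e. about "
      f"{0.1 * np.mean(dist):.1f} px here)")

train, test = rp.split_dataset(ds, 0.8, seed=42)
print(f"80/20 split: {len(train)} training / {len(test)} test frames")
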