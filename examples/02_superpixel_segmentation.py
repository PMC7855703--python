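"""Superpixel sizing and SLIC segmentation of a slide.

The superpixel count adapts to image size as N = ceil(S / U) so the mean
superpixel area (U = 1500 px by default) — and hence its physical size — is
constant across slides.
"""

import warnings

import numpy as np

import histomap as hm

warnings.simplefilter("ignore")

# sizing rule across slide sizes, at the default density
for side in (8000, 12000):
    n = hm.superpixel_count(side * side)
    print(f"{side}x{side} slide -> {n} superpixels (mean area {side*side/n:.1f} px)")
print("physical side of a 1500 px superpixel at 2.016 um/px:",
      f"{hm.physical_superpixel_size(1500, 2.016):.1f} um")

# segment a synthetic slide
mosaic = hm.generate_mosaic(hm.melanoma_like_spec(seed=7))
n_target = hm.superpixel_count(mosaic.image.shape[0] * mosaic.image.shape[1])
seg = hm.segment_slic(mosaic.image, n_target)
areas = np.array([r.pixel_count for r in seg.records])
print(f"\n512x512 mosaic: target {n_target}, achieved {seg.n_superpixels} superpixels")
print(f"superpixel areas: mean {areas.mean():.0f} px, min {areas.min()}, max {areas.max()}")
print("each superpixel is one contiguous region the CNN will classify as a unit")
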