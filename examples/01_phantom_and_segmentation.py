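"""Generate a synthetic MLO phantom and recover its tissue classes.

Builds one phantom with known ground truth, runs the preprocessing chain
(denoise, enhance, breast mask, pectoral removal) and the four-class fuzzy
C-means segmentation, and reports how well the recovered labels match the
ground truth.
"""

import numpy as np

from mammospat import PhantomSpec, generate_phantom, preprocess_image, segment_tissue

spec = PhantomSpec(seed=1, noise_sd=0.02)
image, truth = generate_phantom(spec)

pre = preprocess_image(image)
labelmap, fcm = segment_tissue(pre.denoised.pixels, pre.mask)

both = (truth.labels > 0) & (labelmap.labels > 0)
agreement = np.mean(truth.labels[both] == labelmap.labels[both])

print(f"breast area: {pre.mask.breast_area_px} px "
      f"({pre.mask.breast_area_mm2:.0f} mm^2 at {image.pixel_spacing_mm} mm/px)")
print(f"FCM centroids (fatty -> dense): {np.round(fcm.centroids, 3)}")
print(f"class areas (px): {labelmap.class_areas()}")
print(f"percentage density (classes 3-4): {labelmap.percentage_density():.1f}%")
print(f"pixel agreement with ground truth: {agreement:.3f}")
# The centroids should sit near the phantom's four tissue intensity levels
# (0.25/0.45/0.65/0.85) and the agreement near 1: the tissue classes are
# recovered almost perfectly at this noise level.
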