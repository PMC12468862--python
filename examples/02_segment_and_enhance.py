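"""Segment a phantom radiograph and enhance the costophrenic ROI.

Shows the full preprocessing path: binary lung mask, projection-profile
boundaries, the heart-to-costophrenic-angle crop (lower half, resized to
227x227), then histogram stretching + Sobel gradient blending.  The
detected box is compared with the generator's ground truth.
"""

from pleurakit import (EnhanceConfig, PhantomConfig, enhance,
                       generate_phantom, save_image, segment)

sample = generate_phantom(PhantomConfig(seed=11, effusion=True, fill_level=0.5))
roi, box = segment(sample.image)
enhanced = enhance(roi, EnhanceConfig("stretch", "sobel_gradient"))

iou = box.intersection_over_union(sample.truth.lung_box)
print(f"detected lung box : {box}")
print(f"truth lung box    : {sample.truth.lung_box}")
print(f"box IoU           : {iou:.3f}   (1.0 = perfect overlap)")
print(f"ROI shape         : {roi.shape}  (fixed classifier input size)")

save_image("roi.png", roi)
save_image("roi_enhanced.png", enhanced)
print("ROI and enhanced ROI written to roi.png / roi_enhanced.png")
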