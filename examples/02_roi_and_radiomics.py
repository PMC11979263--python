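"""Extract the fixed ROI and the 465 radiomic features for one vessel.

The ROI is the 41-column band around the straightened centerline (the
centerline column +/- 20 px), delineated once per vessel and propagated to
all of its rotational views, padded or cropped to a fixed height and min-max
normalized. Features: 18 first-order + 75 texture values on the original
image and each of its four wavelet bands.
"""

from stenograde import CohortSpec, extract_features, generate_cohort
from stenograde.roi import extract_cohort_rois

spec = CohortSpec(n_patients=3, image_rows=120, seed=3)
images, truths = generate_cohort(spec)
rois = extract_cohort_rois(images, target_rows=107)

roi = rois[0]
print(f"ROI {roi.source}: shape {roi.pixels.shape}, {roi.n_values} values, "
      f"{roi.pad_rows} padded rows")

values = extract_features(roi)
print(f"{len(values)} radiomic features; a few of them:")
for name in (
    "original_firstorder_Mean",
    "original_glcm_Contrast",
    "original_glszm_ZonePercentage",
    "wavelet-HH_glrlm_RunEntropy",
):
    print(f"  {name:<38} {values[name]:.4f}")

# Mean intensity reflects how much bright lumen fills the band; GLCM contrast
# and zone percentage summarize local texture heterogeneity; wavelet-band
# features capture the same statistics at high spatial frequency.
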