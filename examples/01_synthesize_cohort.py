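"""Synthesize a small cohort of straightened-vessel views and inspect it.

Builds 10 patients with the default class mix (no CAD / nonobstructive /
obstructive in roughly 2:4:5 proportion), three vessels each, up to eight
rotational views per vessel with 6% random dropout, and prints the census.
"""

import numpy as np

from stenograde import CohortSpec, generate_cohort

spec = CohortSpec(n_patients=10, image_rows=120, seed=7)
images, truths = generate_cohort(spec)

print(f"{len(images)} views from {spec.n_patients} patients")
for label in ("noCAD", "nonobstructive", "obstructive"):
    n = sum(t.class_label == label for t in truths)
    print(f"  {label:>15}: {n} patients")

worst = {t.patient_id: max(t.max_stenosis_fraction.values()) for t in truths}
print("\npatient  class            worst narrowing")
for t in truths[:5]:
    print(f"{t.patient_id}     {t.class_label:<16} {worst[t.patient_id]:.2f}")

# Every view carries the ground-truth per-row lumen-width profile; its minimum
# is 1 - (worst narrowing of that vessel), the quantity the class is defined on.
img = next(i for i in images if i.truth_stenosis_profile.min() < 0.5)
print(
    f"\nexample obstructive view {img.key}: "
    f"profile min {img.truth_stenosis_profile.min():.2f} "
    f"(narrowing {1 - img.truth_stenosis_profile.min():.2f})"
)
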