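"""Run the selection chain and the two-stage cascade on a synthetic cohort.

Stage A separates no-CAD from CAD images, stage B grades CAD images as
nonobstructive vs. obstructive; a patient's final label comes from per-stage
majority voting over their images. Each stage scales its features, runs the
Spearman-redundancy / rank-sum / LASSO chain, balances classes with SMOTE and
fits a seeded random forest.
"""

import numpy as np

from stenograde import CohortSpec, CascadeModel, compute_metrics
from stenograde.pipeline import prepare_cohort
from stenograde.evaluation import SplitPlan, make_splits

art = prepare_cohort(CohortSpec(n_patients=30, image_rows=120, seed=9),
                     target_rows=107)
splits = make_splits(list(art.labels.index), art.labels,
                     SplitPlan(test_fraction=0.2, inner_repeats=3, seed=0))

pid = art.radiomic.index.get_level_values("patient_id")
x_train = art.radiomic.loc[pid.isin(set(splits.train_pool))]
x_test = art.radiomic.loc[pid.isin(set(splits.test_patients))]

model = CascadeModel.fit(x_train, art.labels, seed=0, n_trees=100)
print(f"stage A kept {len(model.stage_a.selected)} features: "
      f"{model.stage_a.selected[:3]} ...")
print(f"stage B kept {len(model.stage_b.selected)} features")

pred = model.predict(x_test)
report = compute_metrics(
    [art.labels[p] for p in pred.index],
    pred["final_label"],
    scores=pred[["score_noCAD", "score_nonobstructive", "score_obstructive"]],
)
print(f"\nheld-out patients: {report.n_patients}")
print(f"balanced accuracy {report.balanced_accuracy:.2f}, "
      f"macro sensitivity {report.macro_sensitivity:.2f}, "
      f"macro specificity {report.macro_specificity:.2f}")
print("confusion (rows = truth noCAD/nonobstructive/obstructive):")
print(report.confusion)
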