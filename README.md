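# stenograde

Segmentation-free, patient-level grading of coronary artery stenosis from 2D
straightened-vessel (multiplanar-reconstruction style) CCTA images.

Grading coronary stenosis drives therapy decisions, but manual CAD-RADS
scoring is slow and reader-dependent, and most automated approaches hinge on
plaque segmentation. `stenograde` implements a segmentation-free alternative:
each straightened-vessel view is reduced to a fixed rectangle around the
centerline, characterized by handcrafted 2D radiomic features *and* the
latent code of a dense autoencoder, and classified by a two-stage cascade
whose per-image decisions are aggregated per patient by majority voting into
three classes — no CAD (0% stenosis), nonobstructive (< 50%), obstructive
(>= 50%).

The pipeline, per image *x* (an 854 × 41 ROI, 35,014 values):

* **Radiomics** — 465 features: 18 first-order + 75 texture values (GLCM 24,
  GLRLM 16, GLSZM 16, NGTDM 5, GLDM 14; IBSI-style definitions, 25 fixed
  bins) on the original image and its four single-level wavelet bands.
* **Autoencoder** — mirrored dense stacks with width halving
  (AE64: 35014→512→256→128→64→…), ReLU hidden / linear bottleneck / sigmoid
  output, trained with Adam on the MSE between x and its reconstruction x̂;
  the bottleneck activations are the learned features, reconstruction
  quality is scored by SSIM.
* **Selection per sub-task** — Spearman redundancy filter (|ρ| > 0.95) →
  two-sided Wilcoxon rank-sum (α = 0.05) → LASSO (L1 logistic, 5-fold CV,
  one-SE rule), then SMOTE balancing.
* **Cascade** — stage A: no CAD vs. CAD on all images; stage B:
  nonobstructive vs. obstructive on CAD images; 500-tree random forests; a
  patient's label is the per-stage majority over their images, ties broken
  toward the more severe class.
* **Evaluation** — patient-stratified 85/15 split, 30 repeated 80/20
  train/validation splits, balanced accuracy and macro
  sensitivity/specificity/F1/AUC, plus Mann-Whitney/Spearman association of
  selected latent features with clinical covariates.

Because real straightened-vessel CCTA datasets are not publicly deposited,
the package includes a seeded synthetic cohort generator (bright tubular
lumen, focal lesions with controllable narrowing, correlated rotational
views, missing views, plaque-like blobs) whose ground truth drives the test
suite. See `docs/methods.md` for every modeling convention and its
rationale.

## Worked example

```python
from stenograde import CohortSpec, CascadeModel, compute_metrics
from stenograde.pipeline import prepare_cohort
from stenograde.evaluation import SplitPlan, make_splits

art = prepare_cohort(CohortSpec(n_patients=30, image_rows=120, seed=9),
                     target_rows=107)
splits = make_splits(list(art.labels.index), art.labels,
                     SplitPlan(test_fraction=0.2, inner_repeats=3, seed=0))
pid = art.radiomic.index.get_level_values("patient_id")
model = CascadeModel.fit(art.radiomic.loc[pid.isin(set(splits.train_pool))],
                         art.labels, seed=0, n_trees=100)
pred = model.predict(art.radiomic.loc[pid.isin(set(splits.test_patients))])
report = compute_metrics([art.labels[p] for p in pred.index],
                         pred["final_label"],
                         scores=pred[["score_noCAD", "score_nonobstructive",
                                      "score_obstructive"]])
print(report.balanced_accuracy, report.confusion)
```

Output (`examples/04_selection_and_cascade.py` prints the full version):

```
stage A kept 20 features: ['wavelet-LL_ngtdm_Complexity', 'wavelet-LL_ngtdm_Busyness',
                           'wavelet-LL_glrlm_HighGrayLevelRunEmphasis'] ...
stage B kept 33 features

held-out patients: 6
balanced accuracy 0.89, macro sensitivity 0.89, macro specificity 0.92
confusion (rows = truth noCAD/nonobstructive/obstructive):
[[1 0 0]
 [0 2 0]
 [0 1 2]]
```

Five of the six held-out patients of this 30-patient toy cohort are graded
correctly — the one miss is an obstructive patient whose milder vessels
outvote the culprit at stage B, the characteristic failure mode of
majority-vote aggregation. The selected names show which texture statistics
carry the stenosis signal. The other scripts under `examples/` walk through
cohort synthesis, ROI extraction and radiomics, autoencoder compression
(printing the 18,100,160 / 18,091,904 / 18,059,008 encoder parameter counts
of AE64/AE128/AE256 and a held-out SSIM), and the clinical-association
analysis.

A thin CLI chains the stages over on-disk artifacts:

```sh
stenograde simulate -c config.yaml        # images + manifest + ground truth
stenograde extract-roi -c config.yaml
stenograde extract-radiomics -c config.yaml
stenograde train-ae -c config.yaml
stenograde encode -c config.yaml
stenograde train-cascade --mode combined -c config.yaml
stenograde report -c config.yaml
```

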