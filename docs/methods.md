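# Methods

`stenograde` grades coronary artery disease (CAD) severity per patient from
2D straightened-vessel views — the multiplanar-reconstruction (MPR) style
images read in coronary CT angiography — without segmenting plaques. Three
classes follow the therapy-relevant collapse of CAD-RADS: no CAD (0%
stenosis), nonobstructive (< 50%), obstructive (>= 50%). The pipeline is:
fixed rectangular ROI around the centerline → 465 handcrafted 2D radiomic
features and a dense-autoencoder latent code per image → per-sub-task feature
selection and balancing → a two-stage random-forest cascade per image →
per-patient majority voting.

## Synthetic cohorts

Real straightened-vessel CCTA data are not publicly deposited, so the
package ships a seeded generator that emulates the statistical structure the
pipeline assumes rather than the physics of CT:

* **Geometry.** Each vessel is a bright, soft-edged vertical band (lumen) on
  a darker background, with a bright horizontal band near the top playing the
  role of ventricular muscle (so the ROI's upper-bound exclusion rule has
  work to do). Focal lesions narrow the lumen according to a per-row
  lumen-width profile: raised-cosine shoulders, flat floor, per-row maximum
  when lesions overlap. The profile's minimum equals 1 − (max stenosis
  fraction), which defines the class.
* **Class structure.** Default class proportions 2:4:5 over patients
  (≈ 18% / 36% / 45%), three vessels per patient, up to eight rotational
  views per vessel, 6% of views dropped at random (at least one view always
  survives per vessel). Nonobstructive patients draw their worst narrowing
  from U(0.05, 0.45) and obstructive from U(0.50, 0.95); the margins around
  the 0.50 boundary keep small-cohort experiments stable, and the bands are
  configurable for boundary-stress experiments. Disease is systemic: beyond
  the culprit vessel, each remaining vessel is involved with probability
  0.75, its severity drawn up to the culprit's — so a diseased patient's
  images mostly show disease, which is what makes per-image classification
  with patient-level labels (and hence majority voting) work at all.
* **Texture beyond geometry.** Nearly every lesion (90–95%) carries an
  adjacent bright (calcified-like) or dark (soft-plaque-like) blob: visible
  plaque — not lumen narrowing — is what distinguishes minimal disease from
  a normal vessel, and it gives radiomic texture features signal that is not
  purely geometric.
* **Views.** All views of a vessel share one stenosis profile; rotation is
  emulated as small seeded width/intensity jitter plus an independent noise
  realization (true 45° resampling would require 3D volumes, which are out
  of scope).
* **Noise.** Additive Gaussian noise with sd 0.01 on a [0, ~1] intensity
  scale. This value is a realism calibration: straightened CCTA views are
  smooth enough that a dense autoencoder reconstructs them with SSIM around
  0.9; at sd 0.01 the noise-imposed SSIM ceiling is ≈ 0.95, so that regime is
  attainable, while at sd 0.03 it would be capped near 0.79, i.e. the
  synthetic data would be qualitatively noisier than the images the method
  is meant for.

What the generator does **not** emulate: scanner physics, contrast and
windowing variation, anatomy (curvature, branching, variable vessel width),
motion/blooming artifacts, or inter-reader label noise. Passing tests on
these cohorts therefore demonstrate that the pipeline's machinery works and
that its qualitative claims hold under controlled conditions — not that the
real-cohort performance numbers transfer.

## ROI convention

The ROI spans the centerline column ± 20 (41 columns — a 40-pixel span plus
the centerline column itself, which reconciles the "40-pixel-wide rectangle"
description with the 854 × 41 input dimension) and runs from a per-vessel
upper boundary to the bottom of the image. Geometry is delineated on one
view and propagated to all views of the vessel. Vessels shorter than the
target height are padded at the top with the crop's median intensity;
longer vessels are center-cropped with odd excess removed from the top. Both
choices are bookkept (`pad_rows`) and invertible. Default height is 854 rows
(35,014 values flattened row-major); the height is parameterized because the
desk-scale experiments use 107-row images. Intensities are min-max
normalized to [0, 1] **per image** (a zero-range image maps to zeros); the
autoencoder's sigmoid output presupposes this range. Whether dataset-level
normalization would behave differently is untested — per-image is the
package's declared convention.

## Radiomic features

465 features per ROI = 93 × 5 image types (original + undecimated
single-level coif1 wavelet bands LL/LH/HL/HH; first letter = filter along
rows). Per image type: 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM,
5 NGTDM, 14 GLDM, following the IBSI-style definitions; the roster is frozen
in `radiomics/registry.py`. Conventions that were genuinely open and are now
fixed:

* Fixed-bin-count discretization, 25 equal-width bins over each image type's
  own range, re-discretized independently per image type; constant images
  degenerate to level 1.
* GLCM: distance 1, four 2D directions, symmetrized, normalized per
  direction, then averaged (matrix averaging, not count merging); features
  computed once on the averaged matrix. GLRLM likewise averages per-direction
  count matrices after padding to a common maximum run length. This differs
  from toolchains that average per-direction feature values; on homogeneous
  textures the difference is small, and the convention is deterministic and
  documented.
* GLSZM zones and GLDM dependencies use 8-connectivity; GLDM dependence size
  is 1 + the number of equal-level neighbors (alpha = 0), sizes 1..9.
* The extraction mask is the full ROI rectangle — the approach is
  segmentation-free by design, so no lesion mask exists anywhere.
* Wavelet bands are kept at full spatial size (undecimated); the 41-column
  width is odd, so a decimating transform would need padding conventions
  that complicate reproducibility.
* Degenerate values resolve to conventions, never NaN: correlation of a
  homogeneous image is 1, information-measure quantities fall back to 0, a
  non-finite feature raises an error naming the feature and image.

## Autoencoder

Mirrored dense stacks with width halved per layer toward the bottleneck:
AE256 (35014→512→256), AE128 (…→256→128), AE64 (…→128→64). ReLU hidden
layers, linear bottleneck, sigmoid output; MSE loss; Adam with default
learning rate 1e-3 (sweepable over 0.1–0.001), max 300 epochs, batch 48; no
early stopping by default. Encoder-only parameter counts are the reference
complexity numbers (18,100,160 / 18,091,904 / 18,059,008; max pairwise gap
41,152) and `count_params` defaults to `scope="encoder"` accordingly.

The implementation is plain numpy with manual backpropagation and seeded
Glorot-uniform initialization: the models are small dense stacks, CPU
training at reduced scale is the test path, and full bit-reproducibility per
seed matters more here than framework features. Training aborts with a
diagnostic if the loss turns non-finite. The AE trains only on the training
partition (with a 20% validation fraction split off internally) so latent
features never see test patients' images, and it never sees labels at all.
Reconstruction quality is scored with SSIM (Gaussian window, sigma 1.5,
11 × 11, data range 1) on the ROI.

## Selection chain and balancing

Per cascade sub-task, on training rows only (images are the statistical
unit, patient labels broadcast to images):

1. Spearman redundancy filter at |rho| > 0.95: pairs processed in descending
   |rho| (lexicographic tie-break); the member with the higher mean absolute
   correlation to all other features is dropped. Mean correlations are
   computed once on the full training matrix.
2. Two-sided Wilcoxon rank-sum per feature, alpha = 0.05, uncorrected
   (configurable); exact enumeration when both groups are ≤ 20 without ties,
   tie-corrected normal approximation otherwise.
3. L1-penalized logistic regression; the penalty is chosen by seeded
   stratified 5-fold cross-validated deviance at one-standard-error
   parsimony over an 8-point log grid C ∈ [1e-3, 10^0.5]. The grid is capped
   at moderate penalties because near-unpenalized fits are expensive and the
   parsimony rule never selects them; the grid is a parameter. Empty
   selections fall back to the minimum-deviance penalty, then to the best
   univariate feature with a logged warning.

SMOTE equalizes class counts after selection (select-then-balance; the
reverse order is possible but not the default): each synthetic row
interpolates a minority sample toward one of its k = 5 nearest minority
neighbors with a uniform gap; k is reduced with a warning when the minority
class is small.

## Cascade and voting

Stage A (no CAD vs. CAD) trains on all training images; stage B
(nonobstructive vs. obstructive) trains only on images of CAD patients,
using true labels (standard cascade training — stage-A predictions are not
piped into stage-B training). Forests: 500 trees, sqrt-p features per split,
unlimited depth, seeded. At prediction, stage A votes over all of a
patient's images; a strict no-CAD majority ends the cascade, otherwise stage
B votes over all images. Exact ties break toward the more severe outcome
(proceed to stage B; obstructive) — clinically conservative, and a declared
convention where none is established. Voting is per-stage patient majority;
per-image full-cascade voting would be an alternative semantics and is not
the default.

For ROC analysis the two stage scores are chained multiplicatively into
pseudo-probabilities per patient: P(noCAD) = 1 − pA,
P(nonobstructive) = pA(1 − pB), P(obstructive) = pA·pB, with pA and pB the
patient-mean image scores. This is one reasonable construction of a 3-class
AUC from a cascade, not the only one.

## Splits, metrics, clinical association

All splits are by patient and label-stratified: 15% of patients held out for
testing; 30 further 80/20 train/validation splits of the training pool
assess robustness. Balanced accuracy is the unweighted mean of per-class
recall; macro sensitivity/specificity/F1/AUC are one-vs-rest unweighted
class means; classes absent from the truth are excluded with a warning.
Model comparisons across repeated splits use the paired Wilcoxon signed-rank
test. Latent features are aggregated per patient (mean over images; median
optional) before Mann-Whitney tests against binary clinical variables and
Spearman correlation against age, uncorrected for multiplicity
(configurable); subgroups under 3 patients and constant features are
reported as not assessable.

## Desk-scale study sizes

The test suite exercises the full pipeline on a fixed synthetic cohort of 75
patients split 60 train / 15 test (120-row images, 107 × 41 ROIs ≈ an eighth
of the full height, so the ROI spans the whole vessel), a reduced
autoencoder scaled to the input (4387→256→128→64) trained 50 epochs, and
five pipeline seeds; a 20-run
label-permutation experiment checks that training on permuted labels drops
held-out balanced accuracy to chance (1/3). These sizes are the package's
scaled-down study conditions; the full-size defaults (854-row ROIs, 300
epochs, 30 inner splits) remain the configured defaults throughout the API.

## Known limitations

* Synthetic vessels are straight, unbranched, and constant-width outside
  lesions; domain transfer to real MPR images is untested by construction.
* The centerline column is an input (from the generator or manifest); no
  centerline extraction is provided.
* Three-class output only; no 6-level CAD-RADS, vessel-level reporting, or
  probability calibration.
* The radiomic roster matches the printed family counts (18/24/16/16/5/14);
  other toolchains enable slightly different default sets (e.g. 23 GLCM
  features), so absolute feature values should be compared only under
  matched settings.
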