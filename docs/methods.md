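# Methods

This note documents the models, statistics and design choices behind
`cxrcad`: what each component computes, the assumptions it makes, and what
the synthetic test bed does and does not establish.

## 1. Problem setting

A chest-X-ray CAD device takes a case of 1–2 grayscale radiographs and, for
each of 8 clinical output categories (Cardiac, Mediastinum/Hila, Lungs,
Pleura, Bones, Soft Tissues, Hardware, Other), emits a binary
abnormality-present determination and bounding boxes around suspicious
regions. Development labels come from panels of expert readers: for a given
case and category, k of n independent labelers called it abnormal. The
reference standard is the majority vote (k ≥ 2 of n = 3; for general n,
strict majority with ties negative — the even-panel rule is our convention,
as published protocols only define n = 3).

## 2. Pre-processing

Radiographs are cropped to the minimal window whose rows/columns exceed a
black threshold (default 0.0, i.e. any strictly positive pixel ends the
padding), rescaled so the height equals the target (anti-aliased bilinear
when downscaling; plain bilinear upscaling, which only occurs at test
scale), and brought to the target width by symmetric zero padding or a
symmetric center crop (the extra pixel, when odd, goes to the right). Two
profiles exist: full scale (inputs must exceed 1440 px in height,
standardized to 800 × 1024) and test scale (no minimum, default 64 × 80).
The minimum-resolution gate is interpreted as a height requirement since
height is the resize reference axis; this is configurable.

## 3. The analysis network

Each image passes through a shared CNN encoder of B convolutional blocks
(3×3 conv → ReLU → 2×2 max pool). Two taps leave the encoder:

* the **final block** feeds global pooling and a fully connected layer,
  giving one `image_feature_dim` vector per radiograph;
* the **penultimate block** (stride 2^(B−1)) feeds the localization branch.

Per-image vectors are projected by a shared fully connected layer to
`case_feature_dim` and combined across the case's radiographs by
**elementwise max**, making predictions invariant to image order and
duplication, and monotone: adding an image can only raise each embedding
coordinate.

The classification head is a fully connected layer emitting 2×8 values,
mapped through `softplus(x) + 1e−4` to strictly positive (α, β) per
category. Softplus avoids the overflow pathologies of `exp`; the floor
keeps the Beta distribution proper. (α, β) parameterize a beta-binomial
distribution over k-of-n labeler counts; the posterior mean α/(α+β) is the
inference-time score. The localization head is a single 3×3 convolution on
the penultimate maps followed by a sigmoid, one probability map per
category per image; maps are upsampled to pixel coordinates (bilinear by
default, nearest available) for box extraction.

Profiles: the test profile uses blocks of (16, 32, 64) channels with 64-dim
image features and a 128-dim case embedding on 64 × 80 inputs, giving
16 × 20 localization maps; the full-scale profile records the reference
geometry (512-dim image features, 1024-dim case embedding, 800 × 1024
inputs, global average pooling). The image-feature pooling is configurable:
global max pooling is the test-profile default because, with a shallow
encoder and small planted shapes, average pooling dilutes a localized
signal by the image area and the classification branch fails to learn;
a deep residual encoder at full scale does not have this problem, so the
full-scale profile uses averaging. All layers and AdamW are implemented directly
on numpy with explicit backpropagation; analytic gradients are verified
against central differences in the test suite.

## 4. Training

Per case, the joint loss sums over categories
`w_c · BCE_c + NLL_c`, where `BCE_c` is the per-pixel binary cross-entropy
between the predicted map and the ground-truth map (reference boxes
rasterized at localization resolution; positive pixels exactly those inside
a box), averaged across the case's radiographs, and `NLL_c` is the
beta-binomial negative log-likelihood of the observed (k, n), computed in
log-gamma space so it is finite for all valid inputs. The per-category
weights default to 1.0 (published descriptions say "weighted" without
values); they are config-exposed and logged. BCE predictions are clipped at
1e−7.

Optimization is AdamW (default lr 2e−3, weight decay 1e−4 — unpublished,
declared in config) over shuffled batches of 16 cases at test scale (the
full-scale reference uses 64; the smaller default keeps batch memory and
step count balanced at n ≈ 500). An epoch is one full pass with the
remainder batch kept. Augmentation applies horizontal/vertical flips,
rotations (±10°), crops (≥ 90% area), gamma (0.8–1.25) and contrast
(0.9–1.1) with per-transform probabilities; geometric transforms are
applied identically to the ground-truth masks, intensity transforms to the
image only. Rotation range and crop fraction are unpublished; the defaults
above are declared once here. A single seed fans out through
`numpy.random.SeedSequence` to weight initialization, shuffling and
augmentation, so runs are exactly reproducible on CPU.

After each epoch the across-category mean AUC of posterior-mean scores on a
disjoint tuning set is computed (categories with one class are excluded
with a warning); training stops when this metric has not improved for 10
consecutive epochs, and the best epoch's weights are returned.

## 5. Post-processing and operating points

Decision thresholds are calibrated per category on the tuning set to
minimize |sensitivity − specificity| over the exact candidate set (midpoints
of adjacent sorted unique scores plus ±∞ sentinels), ties broken toward
higher sensitivity; a score on or above the threshold yields "present".
Map-binarization thresholds are calibrated to maximize mean IoU on the
tuning set over a 0.05–0.90 grid (published descriptions say only
"pre-computed"). Both are frozen with a calibration fingerprint before any
test-set contact. Boxes are tight bounding boxes of 4-connected
super-threshold components, dropping components below 0.05% of the image
area (speckle suppression; unpublished, configurable); no merging of nearby
components is performed. A "present" call with an empty box list is legal
but logged as a warning.

## 6. Evaluation statistics

AUC is the trapezoidal ROC area, identically the tie-aware normalized
Mann–Whitney statistic (delegated to scikit-learn; validated against
brute-force pair counting). "Overall" metrics micro-average by pooling all
(case, category) pairs; overall sensitivity/specificity pool the binary
determinations made at the frozen per-category thresholds (whether the
published overall operating metrics pooled per-category calls or used one
global threshold is unstated; per-category-then-pool matches the device's
actual outputs). Confidence intervals are 95% percentile bootstrap with
m = 1000, resampling whole cases so all 8 category labels move together
(the resampling unit is unstated in the source material; case-level
resampling preserves within-case correlation). Replicates where a metric is
undefined are skipped up to a 20% cap.

Localization is scored by summed-box IoU: the pixel set covered by the
predicted boxes intersected/unioned with the set covered by the reference
boxes. Overlapping boxes within one side are not double-counted (a raw
summed-area variant is reported alongside for transparency); pairs with
both sides empty are excluded, so aggregation is over true positives.
Subgroup analyses report per-stratum sensitivity or AUC with bootstrap CIs,
suppressing strata with 20 or fewer cases.

## 7. MRMC reader-study statistics

The crossover design assigns, per reader, a stratified near-half of cases
to the aided condition in session 1 and the complement in session 2, so
every (reader, case) is read once per condition. DBM analysis computes each
reader × condition AUC micro-averaged over categories, forms case-jackknife
pseudovalues `n·θ − (n−1)·θ₍₋c₎` (deleting all of a case's category pairs
at once; an O(n log n) incremental Mann–Whitney identity avoids recomputing
each leave-one-out AUC), and fits the three-way mixed ANOVA with condition
fixed and readers/cases random. The test statistic is the quasi-F
`MS_T / (MS_TR + max(MS_TC − MS_TRC, 0))` with Hillis denominator degrees
of freedom by default (`hillis=False` gives the classic Satterthwaite
form); the CI on the LS-mean difference uses `2·MS_den/(r·c)`. Monte-Carlo
validation in the test suite confirms the nominal 5% type-I error and ≥90%
power for a planted ΔAUC ≈ 0.10 at 24 readers × 238 cases.

The DeLong test compares two correlated AUCs on the same cases through
placement-value covariance; it returns an unadjusted two-sided p, and any
Bonferroni correction (α = 0.025 for the two planned group comparisons) is
applied by the report layer. Miss-rate reduction is
`100·[(1−s_u) − (1−s_a)]/(1−s_u)`. Read times are compared by a paired t
test on per-reader mean log read times (reader-level pairing reproduces the
published degrees of freedom, e.g. df = 17 for 18 non-radiologists);
medians and the relative median change are reported on the raw scale. A
reported `t(1, df)` in the literature is the F-presentation of the same
statistic, t² = F(1, df).

## 8. The synthetic test bed

The generator emulates the *structure* of the development and study data,
not radiographic appearance:

* **Images.** 96 × 120 phantoms: a smoothed Gaussian random field
  (σ = 3 px, amplitude 0.06) over a coarse thorax-like gradient (bright
  central column, vertical falloff). Each category plants at most one shape
  with contrast 0.28–0.45 and size 14–30 px. The 8 categories own distinct
  signatures — four parametric families (blob, ring, line, grid-texture) ×
  two polarities (bright/dark) — so a small CNN can separate them. Cases
  have two images with probability 0.3; per-category prevalence defaults to
  0.12, giving tens of positives per category at desk-scale sample sizes
  (a 3%-prevalence screening mix would leave too few positives to learn or
  calibrate on at n ≈ 500).
* **Labels.** Each of n = 3 simulated labelers marks a truly present
  category with probability equal to the panel sensitivity (default 0.9)
  and an absent one at 1 − specificity (default 0.95), independently;
  positive labelers emit the truth box jittered by up to 10% shift/scale.
  The majority vote of this panel is the reference standard. Labeler box
  disagreement is not reconciled: the generator keeps a single truth box
  per abnormality and treats labeler boxes as noisy copies.
* **Reader studies.** Confidence scores follow a binormal latent model:
  `a·y·ability_r + η_case,cat + ε`, with the case effect (τ = 0.5) shared
  across readers and conditions (this is what makes MRMC inference
  non-trivial) and `confidence = 100·logistic(z)`. Because the map is
  rank-preserving, the configured AUC targets hold exactly in law. Defaults
  mirror a 24-reader, 238-case, 8-category study with per-specialty
  unaided/aided AUC targets (radiology 0.865→0.900, internal 0.800→0.895,
  family/emergency 0.740→0.860) and log-normal read times with medians
  107→98.5 s (non-radiologists) and 69.5→67.5 s (radiologists). The latent
  model cannot simultaneously match published AUCs *and* published binary
  sensitivity/specificity operating points — simulated readers' calls at
  the confidence-50 threshold sit at whatever operating point the latent
  geometry implies; explicit sensitivity targets can be set instead when an
  effect on sensitivity at a matched threshold is the quantity under test.

Passing tests on this bed show the *machinery* is correct — losses match
oracles, calibration is optimal, MRMC error rates are nominal, and the
pipeline can learn separable structure end to end. They say nothing about
accuracy on real radiographs, which depends on data and model capacity far
beyond desk scale.

## 9. Numerical choices and degenerate inputs

* Beta-binomial NLL and its analytic digamma gradient are computed in log
  space; validated to 1e−8 against numerical integration.
* All-black images crop to themselves with a warning; empty images are
  errors. One-class AUC inputs raise; one-class tuning categories are
  excluded from the early-stopping mean with a warning; jackknife
  replicates that lose a class fall back to the full-data AUC with a
  warning; bootstrap replicates with undefined metrics are skipped up to a
  20% cap.
* Threshold ties break toward higher sensitivity; box coordinates are
  0-based half-open everywhere.
* Network parameters and convolution arithmetic are float32 (CPU-friendly);
  likelihood terms and statistics are float64.

## 10. Problem sizes

Default desk-scale runs: 500 training / 150 tuning cases for the
learnability check (30 epochs, a few minutes on one CPU); 400/100/200
train/tune/test for the end-to-end pipeline report; 500 null replicates at
10 readers × 80 cases × 2 categories for type-I validation and 200
replicates at 24 readers × 238 cases × 8 categories for power. These sizes
are the package's chosen balance between Monte-Carlo resolution and a
test suite that runs in minutes.

## 11. Known limitations

* No radiographic realism: no anatomy, pathology texture, scanner effects
  or site heterogeneity; generalization claims cannot be made from this bed.
* The numpy network is adequate at test scale only; the full-scale
  profile documents geometry but is not trainable here (no pretrained
  weights, no deep residual implementation).
* DICOM support is read-only, single-frame, linear rescale (no VOI LUT).
* The localization branch is the weakest learner at desk scale: coarse
  maps and extreme pixel-class imbalance cap achievable IoU well below
  what a full-scale system reports.
* The OR (Obuchowski–Rockette) correlated-error formulation of MRMC
  analysis is out of scope; DBM with Hillis df is the single supported
  method.
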