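# Methods

## Problem and model

The toolkit classifies single axial CT slices of pancreatic cystic lesions
into serous (SCN) versus mucinous (MCN) cystic neoplasms.  The deciding
signal is internal architecture: SCNs are microcystic (many small locules
separated by septa — a honeycomb), MCNs are uni- or oligo-locular.  The
pipeline makes that architecture explicit (edge and gradient channels),
summarizes it (texture or CNN features), and classifies with a fused
ensemble.

### ROI geometry

Coordinates are 0-based with boxes inclusive on both ends; "expand by
2 px" therefore moves each box side exactly two indices outward before
clipping to the image.  Patch extraction copies HU values without
rescaling; all intensity normalization happens in the windowing step.
The manual arm fills outside-mask pixels with the lower bound of the
display window (−160 HU at the default window), rendering them as the
darkest displayable tissue.

### Multi-channel conversion

* Windowing: linear map of `[WL − WW/2, WL + WW/2]` to `[0, 1]`, clamped.
  Default WL 40 / WW 400 HU — the standard soft-tissue abdomen window.
  Both are configurable (`window.level`, `window.width`).
* Canny: σ = 1.0 px; hysteresis thresholds 0.1/0.2 expressed as fractions
  of the maximum smoothed-gradient magnitude, so they are invariant to the
  patch's absolute contrast.
* Gradient channel: per-pixel Euclidean norm of the two Sobel derivatives,
  divided by its maximum (all zeros when the patch is constant).  The
  normalization is the minimal monotone "enhancement"; a gamma exponent
  could be added without touching the contract.
* The edge and gradient channels are computed **on the windowed plane**,
  not on raw HU.  Windowing is monotone, so edge positions are unchanged;
  computing after windowing keeps all three channels on one scale.

### Texture features

Defaults (all configurable): GLCM — 32 gray levels by uniform binning of
[0, 1], offsets {(0,1), (1,0), (1,1), (1,−1)}, symmetric normalized
matrices, statistics contrast, correlation, energy (angular second moment
Σp²), homogeneity, entropy (bits).  LBP — P = 8 interpolated neighbors,
R = 1, 256-bin normalized histogram; border pixels are excluded from the
histogram because their circular neighborhoods would leave the patch.
HOG — 64×64 resize, 8×8 cells, 2×2 blocks, 9 orientation bins, L2-Hys.
Gabor — 4 frequencies (0.1–0.4 cycles/px) × 4 orientations, mean and SD of
response magnitude.  Wavelet — Haar, 2 levels, per-subband energy (mean
squared coefficient) and Shannon entropy of normalized squared
coefficients.  Texture extractors consume the windowed channel only.

### CNN features

The CNN is a frozen feature extractor read at its global-pooling layer;
no fine-tuning, because all learning happens in the downstream
classifiers.  The `tiny_cnn` backend (default) is a fixed numpy stack —
three 3×3 convolutions (3→16→32→64 channels, He-initialized from a seeded
RNG), ReLU, 2×2 max-pooling, global average pooling → 64 features — small
enough to run the full pipeline in seconds on one CPU while remaining
fully reproducible offline.  `resnet_pool` (2048-d) and `alexnet_pool`
(256-d) wrap torchvision backbones when a deep-learning runtime is
installed; otherwise they raise a named error pointing at the fallback.
Inputs are bilinearly resized per channel and standardized (zero-SD
channels become zeros).

### Classifier fusion

Base classifiers: KNN (k = 5, odd to preclude vote ties), multinomial
logistic regression ("softmax", L2, C = 1), Gaussian naive Bayes, and SVM
(RBF, C = 1) with Platt-style sigmoid calibration for probabilities.  Each
sits behind a train-statistics-only standardizer.  The positive class is
MCN everywhere — the clinically actionable lesion.

The stacked model trains a random forest (200 trees, unlimited depth,
seeded) on the three base classifiers' positive-class probabilities.
Meta-training uses **out-of-fold** probabilities from stratified 5-fold CV
on the training set — the standard construction that prevents the meta-
learner from seeing a base model's prediction on a point that model was
trained on; the stored out-of-fold matrix makes this assertable.  Only the
positive-class probability per base is used (the other column is
redundant for two classes).  Hard labels threshold the fused probability
at 0.5, ties going to the positive class.

### Evaluation

Precision, sensitivity, specificity, accuracy and F1 come from the 2×2
confusion table; zero-denominator cases return 0 with a warning rather
than raising, so degenerate arms survive batch comparisons.  AUC is
computed from the continuous positive-class score and equals the
Mann–Whitney pair-counting probability (ties ½).  AUC differences between
paired arms can be tested with a sign-flip permutation test
(`compare_auc_permutation`); this is a pragmatic substitute for whatever
test produced the published p-values, which is not named.

Splits: `image` mode is a stratified random split of slices; `patient`
mode (default) assigns whole patients to one side, approximating the 80%
fraction at the image level.  Image mode mirrors the published design but
lets slices of one patient straddle the split, which inflates test scores
when slices are correlated — precisely the situation the phantom cohort
reproduces.

### Seeding

One global experiment seed fans out to per-stage seeds via
`sha256("{seed}:{stage}")` truncated to 31 bits, so the phantom data, the
split, CNN weights, and classifier initialization are all individually
re-derivable and two runs differ in nothing but timestamps.

## The phantom generator

Each synthetic patient owns one lesion: an ellipse (semi-axes 15–30 px in
a 128×128 image, random orientation, slight center jitter) whose interior
is partitioned into locules by the Voronoi tessellation of random internal
seed points — 6–12 seeds for SCN, 1–3 for MCN.  Cell boundaries plus a
2 px rim form the septa/wall.  Noise-free intensities: fluid 10 HU, septa
60 HU, parenchyma 90 HU; additive Gaussian noise σ = 10 HU per slice.
These values are plausible for cystic pancreatic lesions on contrast CT
but are declared, not fitted — no intensity statistics of the original
cohort are available.  A patient's slices share geometry and differ only
in noise, creating intra-patient correlation.  Study-condition defaults
throughout (20 patients per class × 5 slices = 200 images) keep the full
desk-scale experiment under a minute on one CPU.

### What the phantoms do and do not show

They carry the locule-count texture contrast, so a passing pipeline
demonstrably extracts and classifies internal lesion architecture
end-to-end.  They do **not** emulate: organ anatomy, contrast phases,
scanner noise spectra, lesion-size/label correlations — or inaccurate
manual outlines.  The last point matters: with pixel-perfect masks the
manual-outline arm is never degraded by outline error, which is the very
mechanism said to handicap it on real data.  Consequently the phantom
benchmark does not reproduce the manual-vs-multichannel ranking observed
on patient images (here the manual arm can even win, since masking
removes background clutter); both arms' AUCs are reported side by side
and only the discrimination claim (multichannel AUC ≥ 0.90) is asserted.

## Numerical choices and degenerate inputs

* Constant patches: zero gradient, empty edge map, zero HOG, GLCM energy 1,
  entropy 0; correlation of a single-level GLCM is defined as 1.
* Zero-SD channels standardize to zeros; zero-max gradients stay zero.
* GLCM "energy" is the angular second moment Σp² (not its square root).
* LBP thresholding is ≥, so a constant neighborhood yields code 2^P − 1.
* Probability ties at 0.5 classify as positive (MCN), documented once.

## Known limitations

Single-lesion, single-slice 2-D only; no automatic segmentation (an ROI
mask is required input); the permutation AUC test is not the published
statistical test; phantom realism is declared rather than calibrated; the
torchvision backends are untested in environments without torch and
`weights="pretrained"` requires a network to fetch weights once.
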