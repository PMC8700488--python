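# Methods

## Problem and model

The package classifies H&E-stained jaw-cyst section images as
odontogenic keratocyst (OKC, positive) vs. non-keratocyst (negative).
The discriminating histology is architectural — OKC's thin, regular
parakeratinised epithelium with a palisaded basal layer — rather than
stain intensity, so the pipeline is built to expose epithelial texture
to the classifier: a cheap region-selection step removes connective
tissue, two CNN branches see the whole image and the epithelium-only
image respectively, and their softmax confidence scores are averaged.

## Region selection

Images are tiled into a fixed 3×3 grid. Tiling uses floor division
with the last tile of each row/column absorbing any remainder, so
reassembly always reproduces the input resolution; at the nominal
3840 × 2160 acquisition size every patch is exactly 1280 × 720.

Two criteria, both computed on the BT.601 grayscale rendering
(0.299 R + 0.587 G + 0.114 B):

* **Candidate**: patch population variance strictly below the
  arithmetic mean of the nine patch variances. Strict `<` means a
  perfectly uniform image (all variances equal to their mean) passes
  through unchanged.
* **Confirmation**: a strict majority of the patch's pixels strictly
  above the patch's own mean intensity. Bright stroma with sparse dark
  fibres has a left-skewed histogram and passes; ties fail, which is
  the conservative direction (tissue is kept).

Confirmed patches are zeroed in all channels. If all nine patches are
confirmed (sections genuinely devoid of epithelium exist) the fully
zeroed output is produced with a warning rather than an error.

Decisions that were genuinely open: variance is computed on grayscale
(consistent with the confirmation step) with the N-denominator
estimator — since the threshold is the mean of the same nine
quantities, the estimator choice only needs to be internally
consistent. Region selection runs at native resolution before any
resizing, because the patch statistics are defined at acquisition
scale.

## Synthetic data

The generator emulates the two statistical contrasts the pipeline
relies on, not histology itself (no nuclei, no stain physics):

* **Epithelium tiles** (default: the top row of the 3×3 grid, like a
  lining epithelium bordering the lumen): mean gray 140, texture SD 40.
* **Stroma tiles**: bright base (mean 220, SD 3) with 8 % of pixels
  darkened by 30–90 gray levels ("fibres"). The speckles serve two
  purposes: they give stroma a realistic non-zero variance, and they
  skew the intensity distribution left so the majority-above-mean
  confirmation criterion fires deterministically — with symmetric
  noise that criterion would be a coin flip.
* **Class signal**: OKC epithelium carries a horizontal sinusoidal
  band (period 24 px, amplitude 40) mimicking basal palisading;
  non-OKC epithelium is unstructured noise at the same total variance
  (the stripe's variance A²/2 is subtracted from the noise budget).
  Mean brightness is matched across classes, so a classifier must use
  texture, not intensity.

Default canvas is 384 × 216 — a 1/10-scale analogue of the 3840 × 2160
acquisition format — because the tiling logic is scale-free and tests
should run in seconds. Passing tests on this data shows the pipeline's
machinery is correct and that the ensemble protocol works on a
separable texture problem; it says nothing about accuracy on real
slides, where class overlap, staining variation and inflammation
dominate.

## Dataset handling

Splits are stratified per class: shuffle with the seed, floor(0.15 N)
to test, floor(0.15 N) to validation, remainder to training. At the
full study sizes this yields 207 of 1384 positives in the test split;
for the 1273 negatives the floor rule gives 190 (no single rounding
rule yields both of the historically printed counts 207 and 191, so
floor is used consistently and the negative count is simply what the
rule produces). Augmentation — shear 0.2, rotation 20°, zoom 0.5,
horizontal flip, shifts 0.1 (the shift magnitude is not externally
fixed; 0.1 is a common default and configurable) — is drawn fresh per
image per epoch, keyed on (config seed, draw seed), and attaches to
the training split only; pipeline code requesting augmentation of
validation or test data gets an exception. Warps use bilinear
interpolation with nearest-edge fill, chosen so augmentation never
introduces black borders that could be confused with zeroed stroma
patches.

## Models

`build_vgg16` and `build_densenet` are structural descriptions used
for architecture arithmetic and inspection: the 13-convolution census
with filter ladder (64, 64, 128, 128, 256×3, 512×6), five 2×2/stride-2
pools taking 224 → 7, the 25088 → 4096 → 2 head with the convolutional
prefix frozen for transfer learning; dense blocks whose layer *n*
input is the channel concatenation of all previous feature maps
(composite: batch-norm → ReLU → 3×3 convolution), transitions with 1×1
convolution at compression 0.5 plus 2×2 average pooling, and the
N(N+1)/2 connection count (14 365 at N = 169). No pretrained weights
are involved anywhere.

The trainable model is `SmallCNN`, a numpy network: three blocks of
3×3 convolution (16/32/64 channels) + ReLU + 2×2 max-pool, global
average pooling, a 32-unit hidden layer and a 2-unit softmax — about
26k parameters. It trains with Adam (β₁ = 0.9, β₂ = 0.999) on binary
cross-entropy of the positive-class probability, which for a 2-unit
softmax equals categorical cross-entropy; probabilities are clamped to
[1e-7, 1 − 1e-7] in the loss. The backward pass is verified against
central-difference numerical gradients in the test suite. Ties in
max-pooling share the gradient equally among tied positions.

Defaults: batch size 12 (the full-scale training recipes quote 12 for
the main experiments, with an isolated mention of 11; 12 is adopted),
learning rate 1e-4 in `ModelSpec` (the conservative transfer-learning
scale; the value is not externally fixed). For the from-scratch
desk-scale runs the pipeline uses 30 epochs of Adam at 3e-3 with
48 × 48 inputs — small enough that a full two-branch experiment on 200
images runs in about 90 s on one CPU, large enough that the 24-px
banding survives the downscale (≈ 5 px period at 48 × 48).

## Evaluation

OKC is the positive class throughout; a sample is predicted positive
when p_okc ≥ 0.5 (the tie goes positive, documented rather than
load-bearing). Accuracy, precision, recall and F1 follow the standard
formulas; per-class rows are obtained by swapping the positive class,
macro averages are unweighted means, weighted averages are
support-proportional. A metric with a zero denominator is reported as
0 with a logged flag. ROC points are taken at every distinct score
threshold and AUC by trapezoidal integration, which equals the
Mann–Whitney concordant-pair fraction (ties counted half); the test
suite checks this identity by brute force and cross-checks against
scikit-learn. The ensemble is the arithmetic mean of the two branches'
positive-class probabilities.

## Experiments

* **I** — baseline backbone on augmented whole images.
* **II** — second backbone on augmented whole images.
* **III** — same backbone on region-selected images (region selection
  is applied to all splits: unlike augmentation it is part of the
  input representation).
* **IV** — branches II and III combined by score averaging.

A run is a pure function of its configuration and seed: data
generation, splitting, augmentation draws, weight initialisation and
batch order are all keyed on it, and two identical runs produce
byte-identical reports.

## Known limitations

* The numpy CNN is CPU-bound and desk-scale by design; it is not a
  route to clinical-scale accuracy figures, and the VGG16/DenseNet
  descriptions do not execute.
* The synthetic stroma/epithelium contrast is far cleaner than real
  H&E, where inflamed stroma can be textured and epithelium can be
  pale; perfect region selection on synthetic data does not transfer.
* The 3×3 grid is fixed; patches mixing both tissues are kept or
  zeroed whole.
* Splits are image-level; with multiple images per case a patient-level
  split would be needed to rule out leakage, but case identifiers are
  not part of the data model.
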