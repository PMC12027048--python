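# Methods

`swecaf` re-creates an imaging-based tumor stratification analysis end to
end: tumors carrying a high abundance of wound-healing cancer-associated
fibroblasts (WH CAFs, marked by vitronectin/VTN) are stiffer on shear-wave
elastography (SWE), so a two-branch convolutional network fusing the B-mode
ultrasound image and the color elastography display can classify a tumor's
WH CAF level non-invasively. Because the original mouse imaging data are
not publicly deposited, the package ships a synthetic cohort generator that
emulates the statistical structure the analysis depends on; every
experiment in the package runs against that generator.

## Synthetic cohort model

Each tumor carries a scalar VTN fraction in [0, 1], drawn from a
two-component Gaussian mixture (a low-abundance and a high-abundance mode,
equal weights). Mean tumor stiffness in kPa is linear in the VTN fraction
with Gaussian noise, clipped to the 0–100 kPa instrument range:

    stiffness = clip(intercept + slope · vtn + ε, 0, 100),  ε ~ N(0, σ²)

with defaults intercept 8 kPa, slope 45 kPa per unit VTN, σ 4 kPa — placing
low-mode tumors near 17 kPa and high-mode tumors near 30 kPa, a plausible
range for subcutaneous murine tumors, with the required positive
VTN–stiffness coupling. The default cohort has 105 tumors with a
shifted-Poisson number of image pairs per tumor (minimum 1, mean 10).

Per image pair, the tumor cross-section is an ellipse of random orientation
covering 20–60 % of the frame. The in-ROI stiffness field is the tumor mean
plus Gaussian-filtered noise (σ_texture 3 kPa, smoothing length = image
size/16), re-centred so the ROI mean matches the tumor's target exactly
before the final clip; background tissue sits at 5 kPa.

Rendering:

* **Elastography** maps kPa through a fixed piecewise-linear
  blue→cyan→green→yellow→red colormap anchored at 0/25/50/75/100 kPa
  (0 kPa = pure blue = soft, 100 kPa = pure red = hard). The vendor's exact
  map is unpublished; this documented map is the package's convention.
* **B-mode** uses the standard first-order speckle model: a two-level
  echogenicity template (background vs ROI) multiplied by unit-mean
  Rayleigh noise (blended by `speckle_scale`; 0 = noise-free), then
  log-compressed to 8 bits. ROI echogenicity couples weakly to the VTN
  fraction (`gray_contrast_slope`), so the B-mode branch carries partial
  label signal, as a real B-mode appearance plausibly would.

The whole cohort — records and all images — is a pure function of the
configuration including its seed (per-tumor/per-pair streams are spawned
from `SeedSequence`).

What the generator does **not** emulate: acoustic wave propagation, depth-
dependent attenuation and shadowing, probe pressure artifacts, anatomical
heterogeneity, and inter-operator variability. Passing tests therefore
demonstrate that the pipeline is correct and can learn the designed
VTN→stiffness→color signal; they do not certify performance on real
ultrasound data.

## Labeling and splitting

The cohort threshold is the mean or the sample median of all per-tumor VTN
fractions (`threshold_method`, default median: it balances classes and is
the convention used for training labels). A tumor is `high` iff its
fraction strictly exceeds the threshold; ties go to `low`. Splitting into
train/validation/test at 3:1:1 happens at the tumor level so no tumor's
image pairs straddle splits. Split sizes come from largest-remainder
rounding (105 → 63/21/21); with stratification (default on) per-class
floors are topped up by largest fractional part under the constraint that
global split sizes stay exact, keeping every split class-balanced within
one tumor.

## Model

Each modality runs through its own feature extractor of structurally
identical blocks — conv 3×3 (stride 1, pad 1) → batch-norm → ReLU → 2×2
max-pool — ending in 7×7 adaptive average pooling. Flattened features are
concatenated and classified by linear(256) → ReLU → dropout(0.2) →
linear(64) → ReLU → dropout(0.2) → linear(2). The two logits go through a
softmax; `p` is the probability of the `high` class, so the training loss
(two-class cross-entropy) reduces to the binary form
L = −[y·log p + (1−y)·log(1−p)], with probabilities clamped at 1e-7.

Design points that were genuinely open and how they were fixed:

* **Channel widths / depth.** Four blocks at [16, 32, 64, 128] by default
  (224→14 spatial reduction before the 7×7 adaptive pool); desk-scale runs
  use two blocks [8, 16] on 64×64 inputs. Fully configurable.
* **Branch parameters are independent**; only the architecture is shared.
* **Grayscale branch takes 1 channel, elastography 3** (the color display
  is what the classifier sees; the kPa field stays in the manifest for
  validation).
* **Initialization** is seeded He (fan-in) normal.

The layers, backprop, and the momentum-SGD optimizer are implemented as a
small NumPy engine (`swecaf.nn`); forward/backward passes of every layer
are verified against finite differences in the test suite.

## Training protocol

Mini-batch SGD with momentum 0.95; random horizontal and vertical flips
(p = 0.5 per axis) applied with the *same* decision to both modalities of a
pair; validation and test data are never augmented. The full-scale protocol
trains 200 epochs and grid-searches learning rate
{1e-2, 1e-3, 1e-4, 1e-5, 1e-6} × batch size {2, 4, 8, 16, 32, 64, 128}
(35 cells), selecting the cell — and, within a run, the epoch — with the
highest validation sum of image-level AUC + accuracy + sensitivity +
specificity (ties: earliest epoch / first cell in row-major order). No
weight decay, no schedule, no class re-weighting (the median threshold
keeps classes near-balanced).

## Evaluation

Hard predictions use a 0.5 cutoff on the softmax `high` probability. Image
level scores every pair; tumor level aggregates each tumor's image-level
hard labels by majority vote, breaking even votes by comparing the tumor
score (mean image probability; vote-fraction scoring is an option) to the
cutoff. AUC is the rank-based (Mann–Whitney) statistic with ties counted
half, identical to trapezoidal ROC integration. Undefined metrics (a class
absent from the evaluated units) are flagged, never silently zeroed.
Cross-validation is tumor-grouped and stratified; each fold trains for a
fixed number of epochs with final-epoch weights — no inner validation
split, so the held-out fold never influences selection — and k defaults
to 5.

## Saliency

Grad-CAM per modality branch at the last convolutional feature map (final
ReLU before the last max-pool): channel weights are the spatial means of
the target-class logit's gradients; the map is the rectified weighted
channel sum, bilinearly upsampled to input size and max-normalized
(identically-zero maps are flagged instead of normalized). Fusion happens
after flattening, so a joint map is ill-defined; both branch maps are
emitted. The quantitative localization check uses the elastography branch,
which carries the stiffness signal the classification is built on; on the
separable cohort its saliency mass concentrates inside the tumor ROI for
the large majority of correctly classified pairs, whereas the B-mode
branch — nearly uninformative on that cohort — shows no such concentration.

## Problem sizes and numerical choices

Desk-scale experiments (the package's standard test profile) use 60-tumor
cohorts of 64×64 images with channels [8, 16] and 30 epochs, or smaller;
these sizes were chosen as the smallest at which the learning, ablation,
and saliency behaviors are stable and quick to reproduce on a single CPU.
The engine computes in float32; seeds fan out from a single global seed via
`SeedSequence` counters so every stage is independently reproducible.
Known limitations: no GPU path, one conv layer per block, no pre-trained
backbones or attention fusion, and no calibration or confidence-interval
analysis on the reported metrics.
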