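# Methods

## Problem setting

`seedspectra` implements an end-to-end analysis for identifying seed
varieties from near-infrared (NIR) hyperspectral images. A line-scan NIR
camera produces a cube of raw intensities (rows × cols × bands, here
spanning roughly 942–1646 nm); single seeds lie separated on a dark
background. The analysis proceeds: reflectance calibration → per-seed
segmentation → pixel-spectrum preprocessing → per-seed mean spectra →
dimensionality reduction / band selection → seven-way classification with a
battery of eleven models compared on identical data partitions.

## Reflectance calibration

Raw intensity is converted to relative reflectance with white
(near-100 % reflectance target) and dark (shutter closed) reference frames:

    R = (I_raw − I_dark) / (I_white − I_dark)

Pixels where white equals dark (dead detector elements) are set to 0 and
counted in the log rather than raising — dead pixels are routine in NIR
InGaAs cameras. Because specular highlights can push R above 1, clipping
to [0, 1] is applied by default but can be disabled. References supplied as
a single scan line are broadcast along the scan axis.

## Segmentation

Seeds are separated from the background by thresholding the gray-scale
image at a single band, 1200 nm by default (a band with strong
seed/background contrast). The threshold is Otsu's method by default, with
a fixed-value alternative for exact reproducibility. Connected components
(8-connectivity, minimum area 20 px, both configurable) become seeds,
numbered in raster order of their topmost-leftmost pixel so the numbering
is deterministic. The outer ring of each seed — pixels mixed with
background and shadow — is removed by morphological erosion with a disk;
the default ring width is 2 px. Erosion extent is a free parameter: the
appropriate value depends on the instrument's point-spread function and
magnification, for which no general value exists.

## Spectral preprocessing

Order of operations at the pixel level: wavelet smoothing → area
normalization → per-seed averaging.

* **Wavelet smoothing** decomposes each spectrum with a Daubechies-10
  wavelet to level 3 (symmetric boundary extension) and reconstructs from
  the approximation coefficients only — all detail coefficients are
  removed, which is the simplest reproducible denoising rule;
  soft-thresholding of the details is available as an option. A level-3
  db10 decomposition needs at least 152 bands; shorter spectra raise an
  error naming the minimum.
* **Area normalization** divides each spectrum by its discrete
  (unit-spacing) sum so rows sum to 1. This cancels any global
  multiplicative illumination factor per pixel. Using the unit-spacing sum
  rather than a trapezoidal integral over nm differs only by a constant
  factor, which normalization absorbs.
* **Per-seed mean**: the arithmetic mean over a seed's pixel rows
  represents the seed in all seed-level models.

Each step appends a provenance string to the table so the pipeline order is
auditable (and asserted in tests).

## Pixel-wise PCA, score images, effective wavelengths

PCA is fit on column-centered pixel spectra (no unit-variance scaling —
reflectance bands share a scale, and scaling would inflate noisy bands).
With more rows than `max_pixels` the mean/loadings are estimated on a
seeded uniform subsample while scores are still produced for every row.
The sign of each loading column is fixed by making its largest-magnitude
entry positive, so score images are reproducible across runs and BLAS
builds. Score images color each foreground pixel by its score through a
fixed colormap scaled to the foreground range, with a neutral background.

Effective wavelengths are chosen from the loadings of the first 10
components: per component, strict local maxima of |loading| along the
wavelength axis whose magnitude is at least θ times that component's peak
|loading| are selected; the union over components is deduplicated and
sorted, with each wavelength remembering its source components. The
default θ = 0.5 reproduces a "prominent loading extrema" reading and
typically retains a few dozen of 200 bands on the synthetic data; adjacent
selected wavelengths are allowed (no minimum-spacing rule). θ is exposed
because no universally correct value exists — the trade-off between
compactness and coverage belongs to the analyst.

## Classifiers

* **PLS-DA**: PLS regression of a one-hot dummy matrix on the spectra,
  decoded by argmax. Class k (of K) carries its 1 in position K−1−k, i.e.
  the classes 0…6 map to the bit strings 0000001 … 1000000. The PLS core
  is a SIMPLS implementation (nested components, so one decomposition
  yields predictions at every LV count), which makes the leave-one-out
  selection of the LV count — up to min(30, features, n−2) — cheap. For a
  single response SIMPLS coincides exactly with NIPALS PLS, which the test
  suite exploits as an independent cross-check against scikit-learn; at
  full rank PLS reproduces the least-squares solution, the second
  cross-check.
* **Logistic regression**: one-vs-rest, L2 penalty, C = 1 (scikit-learn).
* **SVM**: RBF kernel with a stratified 5-fold CV grid search over
  C ∈ 10⁻²…10⁴ and γ ∈ 10⁻⁴…10² (7 × 7 log-spaced by default). Ties break
  toward smaller C, then smaller γ. Rows are canonically sorted before
  fold construction so the search is invariant to input row order.

## Deep models

Two 1-D convolutional architectures, implemented in a compact numpy layer
framework (im2col convolutions evaluated as BLAS matmuls, explicit
backward passes, float32 arithmetic):

* **Self-design CNN**: two convolution blocks (conv k3/s1 + ReLU +
  max-pool 2/2) with 64 and 128 kernels, then dense layers of 512, 128 and
  7 neurons and a softmax output. The ReLU-activated 128-neuron layer is
  the deep-feature representation.
* **ResNet-1D**: a 1×1 entry convolution (64 channels, batch-norm + ReLU),
  four residual blocks with channel counts 64/128/256/512 — each block two
  k3 convolutions with batch normalization, blocks 2–4 downsampling by
  stride 2 with 1×1 projection shortcuts, block 1 with identity shortcuts
  — then global average pooling (the 512-d deep feature) and a 7-neuron
  softmax head. This mirrors the standard 2-D ResNet design transposed to
  one dimension; batch normalization can be disabled by flag.

All k3 convolutions use same-length padding so short inputs (e.g. a few
dozen selected wavelengths) survive the depth. Max-pool windows (2/2) and
the downsampling scheme are design choices of this package. Weights use He
initialization from a seeded generator.

Training minimizes softmax cross-entropy with SGD and classical momentum
(defaults: lr 0.01, momentum 0.9, batch 64), with early stopping on
validation accuracy and restoration of the best-validation weights.
Inputs are z-scored per band on the training set by default (stored inside
the model so downstream feature extraction is consistent). All shuffling
derives from the config seed; training is exactly reproducible on one
machine. A non-finite loss raises a training error naming the epoch.

Every backward pass is verified against central-difference numerical
gradients in the test suite.

## Evaluation protocol

Seed-level spectra are partitioned once into calibration : validation :
prediction at 3:1:1, stratified by class (largest-remainder apportionment,
so per-class counts match the ratio within one sample). The identical
partition feeds all 22 grid cells — 11 models × {full spectra, effective
wavelengths}:

* pure LR / PLS-DA / SVM on the spectra;
* CNN-SoftMax and ResNet-SoftMax trained end-to-end (calibration set for
  gradients, validation set for early stopping);
* CNN-/ResNet-{LR, PLS-DA, SVM} fit on features from the *frozen* trained
  network. The network never sees prediction-set labels, so hybrid models
  inherit no leakage.

Per cell the report carries the three split accuracies
(100 · correct / total) and confusion matrices; accuracy always equals
100 · trace/total of the cell's own confusion matrix. Per-cell RNG seeds
derive from the master seed plus a CRC of the cell name, so cells are
isolated but the whole run is reproducible (two runs with one master seed
emit identical JSON). Within one experiment run the SVM search uses a
coarser 4×4 log-spaced subset of the same (C, γ) decades, since the
experiment fits six SVMs per run.

## Synthetic data: what it emulates, and what it does not

No public accession of seed hyperspectral cubes accompanies this kind of
analysis, so the package ships a first-class generator:

* **Spectra.** All classes share one smooth base reflectance curve — a
  gentle quadratic trend plus Gaussian features at 1119 nm (peak), 1204 nm
  (valley), 1308 nm (peak) and 1470 nm (valley), the landmark NIR
  absorption features of seed tissue (C–H second overtone, O–H first
  overtone). Each class offsets the base by ±`deviation` on its own random
  set of discriminative bands. `deviation = 0` is the exact null.
* **Scenes.** Seeds are random non-overlapping ellipses (random radii and
  orientation) on a near-dark background with small jitter, so
  thresholding is non-trivial but reliable. Raw intensities are
  synthesized as `dark + (white − dark) · reflectance`, so the standard
  correction recovers reflectance exactly in the noiseless case (the
  round-trip is tested to 1e−10).
* **Noise.** A per-pixel lognormal multiplicative factor (illumination,
  constant across bands — which area normalization should cancel) and
  per-pixel-per-band additive Gaussian noise (detector).
* **Defaults.** 200 bands over 942–1646 nm; deviation 0.05 with additive
  noise 0.01 defines the strong-signal regime (signal-to-noise 5) used in
  the end-to-end tests; multiplicative noise 2 %.

What the generator does *not* model: seed chemistry and its covariance
structure across bands, fuzz/hull texture, spatial gradients within a
seed, detector nonlinearity, and band-correlated noise. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
the models can exploit class-mean differences under realistic noise — not
that any particular accuracy would be attained on real seed images.

## Problem sizes and numerical choices

* End-to-end grid checks run at 120 seeds per class (840 seed spectra,
  3:1:1 split) with networks capped at 30 epochs (patience 8); the
  reproducibility check uses 40 seeds per class at 5 epochs; the
  acceptance script uses 100 seeds per class at 25 epochs. These sizes are
  the package's chosen test conditions; the strong-signal regime is easy
  enough that all 22 cells clear 85 % prediction accuracy well before the
  epoch cap.
* Degenerate inputs: empty foreground masks warn and yield zero seeds;
  seeds eroded to nothing are dropped and the survivors renumbered;
  nonpositive-area spectra are dropped with a logged count; wavelength
  queries beyond the axis warn but resolve to the nearest band (ties to
  the lower index).
* PCA uses an economy SVD; explained fractions are taken against total
  variance, so they sum to 1 only over all possible components.
* Softmax is evaluated shift-stably (max subtraction). Prediction ties
  resolve to the lowest class index.

## Known limitations

* The generator's class differences are sparse band offsets; models that
  exploit smooth shape differences (common between real varieties) are not
  stressed.
* LOO-based LV selection is optimistically biased on small n, as usual;
  the permutation-null tests bound the effect at chance level.
* The numpy networks target CPU-scale problems (hundreds to thousands of
  spectra); there is no GPU path, data augmentation, or transfer learning.
* Erosion ring width, the selection threshold θ, and the noise levels are
  free parameters, not estimates of any instrument.
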