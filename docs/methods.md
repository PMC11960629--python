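# Methods

`octsex` is a simulation-backed re-implementation of an OCT-plus-CNN chick
vent-sexing pipeline.  Day-old chicks cannot be sexed reliably from the
outside; the discriminative anatomy is inside the cloaca, where males carry
a phallus with three small cones and females only two.  The pipeline
images that anatomy with simulated spectral-domain optical coherence
tomography (SD-OCT), trains a small convolutional network on the resulting
B-scans, and evaluates it with a three-outcome confusion-matrix surface
(female / male / not-detect).  Because the original 1200-image Korat-chick
dataset is private, the package ships a synthetic-cohort generator that
emulates the study design end to end; real 8-bit grayscale images with a
CSV manifest can be substituted at the preprocessing stage.

## Phantoms and cohort design

A phantom is a parametric cloacal cross-section in physical units (µm):

* a tissue surface at 500–900 µm depth with a parabolic lateral bow
  (20–150 µm sag);
* three sub-surface layers (80–300 µm thick, backscatter amplitude
  0.35–0.55 at the top, decaying ×0.55 per layer) attenuated as
  `exp(-µ·d)` below the surface with µ ∈ [2·10⁻⁴, 8·10⁻⁴] per µm;
* two or three bright parabolic cones (width 200–600 µm, height
  150–400 µm, amplitude 0.65–0.95) protruding above the surface, spaced
  650–900 µm around the lateral field center.

The cone count is the ground truth: three iff male, two iff female.  No
physical measurements of the real cone geometry are published anywhere we
know of; the ranges above are chosen so cones are resolvable at the
system's 4 µm/px pitch and still visible after the 13× downscale to the
network's 75×64 input, and all of them are configurable.

A cohort mirrors the study design: 30 chicks (15 male / 15 female), 50
frames per chick, of which 40 survive quality selection → 1200 images.
Anatomy is sampled once per chick; each frame jitters the base geometry by
±10 %, emulating repeated scans at slightly different cloacal locations.
A configurable fraction of frames (default 5 %) is rendered with the cones
occluded ("ambiguous"); these populate the not-detect *true* class at
evaluation and are excluded from training.  Cohort generation is a pure
function of the spec and seed.

## OCT forward model and reconstruction

The simulator implements ideal SD-OCT physics: at each lateral position the
detected spectrum is `S(k)·|r_R + Σ_z a_z e^{2ikz}|²`, with a Gaussian
source envelope `S(k)` (840 nm center, 31 nm FWHM) sampled uniformly in
wavenumber so that one FFT bin equals one 4 µm depth pixel.  Reflectivity
values act as field amplitudes scaled by 10⁻³ relative to the reference, so
cross terms dominate and sample autocorrelation is negligible (the linear
imaging regime).  The source bandwidth is not a published system parameter;
31 nm is chosen because the coherence-length formula
`l_c = (2 ln 2/π)·λ₀²/Δλ = 4 ln 2/Δk` then gives 10.0 µm at 840 nm,
matching the system's stated ~10 µm depth resolution — and the simulated
point-spread function is verified against that closed form in the tests
(measured 10.4 µm FWHM, within the 20 % band).

Reconstruction follows the standard chain: subtract the reference-arm
background spectrum (otherwise its DC peak would set the normalization
factor), FFT over wavenumber, take the magnitude over positive depth bins
(the envelope), crop to the stored 1000×600 window (the acquisition grid is
1000×1000; the top 600 rows contain the tissue), divide by the per-image
envelope maximum (scale-factor normalization, max exactly 1.0), then map to
8 bits with a dB-linear ramp `u8 = round(255·clip(1 + dB(x)/|floor|, 0, 1))`
with a −50 dB floor: amplitude 1 → 255, anything at or below the floor → 0,
monotone in between.

Speckle is modelled as multiplicative gamma noise of unit mean and relative
standard deviation `speckle_scale` on envelope amplitudes, plus an optional
Rayleigh detector floor expressed relative to the envelope maximum.  This
captures the first-order statistics of coherent noise but not its spatial
correlation, dispersion, sensitivity roll-off or motion artifacts — so a
classifier that works here has been shown to read anatomical structure out
of noisy, attenuated, log-compressed images, not to survive every artifact
of a physical scanner.

## Preprocessing

Enhancement: 3×3 median filter (impulsive speckle outliers), percentile
contrast stretch (1–99.5 %), unsharp masking — each disableable; all are
no-ops on flat input.  Quality selection emulates the manual "clarity and
structural visibility" screen with the mean Sobel gradient magnitude as the
score, keeping the best 40 of 50 frames per chick (ties broken by frame
index).  Augmentation (training split only, after the split, to avoid
leaking augmented test frames) applies rotation within ±15°, horizontal
flips — mirroring the lateral axis preserves the cone count — and optional
brightness/contrast normalization.  The rotation range and flip axis are
conventions: no canonical values exist.

Resizing uses area averaging (Pillow BOX) for downscales, which preserves
the integrated energy of the small bright cones far better than point
sampling at 13× reduction, and bilinear interpolation for upscales.
Printed sizes are width × height (lateral × depth): a 1000×600 B-scan is an
array of shape (600, 1000) and the 75×64 network input is (64, 75).  One
convention, asserted by the classifier's input validation.

The 80/20 split has two modes: `by_image` (stratified by frame label; the
study's 1200 images give exactly 960/240) and `by_chick` (all frames of a
chick share a split, stratified by sex: 24/6 chicks at the defaults).
Whether the original split was image- or chick-level is not documented;
`by_chick` is the default here because image-level splitting lets the
network recognize individual animals rather than anatomy.

## Classifier

The network is fixed: three blocks of 3×3 same-padding convolution
(32, 64, 128 filters) + ReLU + 2×2/stride-2 max-pooling, 25 % dropout,
flatten (9×8×128 = 9216 features at 75×64 input), a 256-unit ReLU layer,
50 % dropout, and a 2-unit softmax (female = index 0, male = index 1).
Training: categorical cross-entropy, Adam at learning rate 10⁻⁴, batch
128, up to 1000 epochs, early stopping when validation loss fails to
improve for 50 consecutive epochs, with best-validation-loss weights
restored.  The validation set is a held-out 10 % of the *training* split,
never the test split.  The implementation is pure NumPy with hand-written
backward passes; gradient correctness is established by finite-difference
checks, and training is deterministic given the seed.

The published system reports a third "not detect" outcome without
describing its mechanism.  Here it is an explicit confidence rule: a frame
is rejected when the winning softmax probability falls below τ
(default 0.6).  With two classes the winner always has probability ≥ 0.5,
so τ ≤ 0.5 makes rejection unreachable — the rule is a stand-in, exposed
as a parameter, not a claim about the original system.

## Evaluation

The confusion matrix is 3×3 (true × predicted over female/male/not-detect).
Per-class precision, recall and F1 use the usual column/row/harmonic-mean
definitions with undefined ratios reported as 0.  Macro averages run over
classes with nonzero support only; weighted averages weight by support,
which makes weighted recall algebraically equal to overall accuracy
whenever every evaluated sample's true class participates — an identity
the test suite checks against a brute-force loop implementation to 1e-12
on random matrices.  The image-size sweep retrains a fresh seed-controlled
model per size over the published list (1000×600 … 75×64), optionally
averaged over several seeds because single CNN runs on small cohorts are
noisy; the 1000×600 row is supported but its fully connected layer holds
~3·10⁸ parameters, so desk-scale runs restrict the sweep to ≤ 224×224.

## Desk-scale study conditions

Training the full 1200-image cohort at 75×64 for up to 1000 epochs is a
GPU-scale job; the package's verification runs use reduced conditions
chosen once:

* **Bookkeeping run** — the full 30×50→40 design simulated on a coarse
  scan grid (200 A-lines × 200 depth px at 20 µm pitch, 512 spectral
  samples); counts, selection and splits are resolution-independent.
* **Parameter recovery** — 16 chicks × 10 frames (keep 8), no ambiguous
  frames, by-chick split, 75×64 input, Adam at 10⁻³ with batch 16 for at
  most 50 epochs.  On the *well-separated* preset (cone amplitude
  0.85–0.95, speckle 0.03–0.08, reduced nuisance anatomy variation) the
  network recovers sex at ≥ 90 % test accuracy.  On the *high-noise*
  preset (cone amplitude 0.02–0.06 under speckle 1.2–2.0 and a 0.3
  detector floor) accuracy falls toward chance — evidence that the
  pipeline measures anatomical signal and that the by-chick split leaves
  no label side channel.  The learning-rate/batch change from the
  published regime is a deliberate desk-scale adaptation: 50 full-batch
  epochs at 10⁻⁴ are too few optimizer steps to converge on 100-odd
  images.

## Numerical choices and degenerate inputs

* Spectra are float64; the B-scan batch path and network are float32
  (float64 is available for gradient checks).
* `normalize_bscan` rejects all-zero envelopes (no scale factor);
  noise-only frames normalize to their own noise maximum and render as
  featureless grey.
* Max-pooling floor-halves odd dimensions (75 → 37) and routes gradients
  to the first maximum on ties; inputs below 8 px per axis are rejected
  (they cannot survive three poolings).
* Quality-selection and split ties break deterministically (frame index,
  sorted chick ids).
* Early stopping counts *strict* improvements; a constant validation loss
  therefore halts training at epoch patience + 1.

## Known limitations

The phantom is a two-dimensional cartoon: no feather shadows, saline
artifacts, probe tilt, motion, or real anatomical diversity across breeds.
Passing the recovery tests shows the pipeline is correct and leak-free on
images whose difficulty is controlled by explicit noise dials; it does not
certify the published real-data accuracy (79 %), which cannot be reproduced
without the private dataset and is out of scope here.
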