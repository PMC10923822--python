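# Methods

## Problem and pipeline

Cardiomegaly screening on a posteroanterior chest radiograph reduces to a
single geometric quantity, the cardiothoracic ratio

    CTR = (maximum horizontal cardiac diameter) / (maximum horizontal thoracic diameter),

with the call *cardiomegaly* when CTR > π and *normal* otherwise (strict
inequality; π = 0.50 by default, 0.55 under the stricter reading
protocol).  `ctrseg` estimates both diameters from two independent binary
segmentation models — one for the cardiac silhouette, one for the lung
fields — by taking the widths of the tightest axis-aligned bounding boxes
of the post-processed masks.  The decisive accuracy bottleneck is
segmentation quality, and pixel-annotated chest radiographs are scarce,
which motivates the semi-supervised training scheme below.

## Segmentation networks

Each model is a skip-free encoder–decoder built from one *convolutional
block*: 3×3 convolution (stride 1, shape-preserving) → batch
normalization → ReLU → CBAM attention (channel gate with a shared
two-layer MLP at reduction ratio 16, then a spatial gate with a 7×7
convolution).  The encoder stacks three blocks per stage followed by 2×2
max-pooling over five stages with filter counts 16/32/64/128/256; a
299×299×3 input yields a 9×9×256 latent (299→149→74→37→18→9).  The
decoder mirrors this with stride-2 transposed convolutions (each followed
by batch normalization and ReLU), then a 3×3 convolution to one channel,
batch normalization, and a sigmoid.  Placing batch normalization directly
before the output sigmoid is unusual; it is implemented literally because
it is part of the architecture contract, not "corrected".

The transposed-convolution padding must invert the encoder's
floor-halving chain: an even target size is produced with `same` output
sizing (out = 2·in), an odd one with `valid` (out = 2·in + 1).  For the
299 input this reproduces the fixed pattern same/valid/same/valid/valid;
for any other admissible input size the pattern is recomputed
automatically, which is what makes 64- and 128-pixel desk-scale models
possible.  Sizes whose halving chain collapses to zero are rejected.

No deep-learning framework is used: the layers, CBAM, and Adam live in a
small numpy engine (`ctrseg.nn`) with hand-written backward passes,
verified against central-difference gradients in the test suite.
Convolutions use im2col + BLAS matmul; activations and parameters are
float32 (float64 in gradient tests).  Weights are He-uniform from an
explicit seeded generator; biases start at zero.  Batch-norm defaults are
momentum 0.99 and epsilon 1e-3 (configurable; see "Desk-scale choices").

## Cross-consistency semi-supervised training

Training uses a labeled pool of n image/mask pairs and a much larger
unlabeled pool of m images.  One shared encoder E feeds two decoders of
identical architecture: the main decoder D sees every latent; the
auxiliary decoder D_aux sees k = 3 perturbed copies of each *unlabeled*
latent, one per perturbation:

* **F-Noise**: z′ = z + z ⊙ N, N ~ U(−0.3, 0.3) elementwise;
* **F-Drop**: threshold the per-sample min–max-normalised channel mean
  at γ ~ U(0.6, 0.9) and zero every spatial position at or below it
  (as specified, the *most active* regions survive; `fdrop_invert`
  switches to dropping them, the convention of the original
  cross-consistency work);
* **Dropout**: elementwise zeroing at rate r ~ U(0.1, 0.7), survivors
  unscaled by default.

The supervised loss is the labeled-batch mean of BCE + Dice loss; the
consistency loss is the mean squared disagreement between the main
decoder's unlabeled outputs (treated as fixed targets — no gradient
flows through them) and the auxiliary outputs.  The total
L = L_S + ω_U·L_U uses the Gaussian ramp-up
ω_U(t) = exp(−5(1 − t/L)²) for t < L, 1 afterwards, with ramp length
L = 50 epochs: early in training the main decoder's unlabeled outputs
are noise, so their weight starts near exp(−5) ≈ 0.0067.  Gradient
routing: L_S updates D and E; ω_U·L_U updates D_aux and E.

As printed, the consistency distance is a per-pair pixel *sum*, which
exceeds the pixel-mean supervised loss by roughly the image area.  Both
behaviours are implemented; the loss module defaults to the literal sum
and the trainer defaults to the pixel-mean variant
(`unsup_pixel_mean=True`) so the two encoder gradients have comparable
scale.  A single auxiliary decoder serves all k perturbations
(`aux_decoders` is exposed but only 1 is supported).

Batch composition: with total batch size bs (default 16),
δ = (n+m)/bs, bs_l = ⌊n/δ⌋, bs_u = ⌈m/δ⌉, computed in exact integer
arithmetic so bs_l + bs_u = bs always holds.  At the reference pool
sizes (n = 247, m = 9763) the floor yields bs_l = 0; bs_l is clamped to
1 (bs_u = 15) and the plan flagged, since a semi-supervised step needs
at least one labeled sample.  An epoch is one pass over the unlabeled
training pool; the labeled pool cycles with reshuffling.  Validation
splits are 20% of the labeled pool (stratified by image-level label when
available, round-half-away counting: 247 → 198/49) and 10% of the
unlabeled pool.  The optimiser is Adam (lr 1e-3, betas 0.9/0.999).
Model selection keeps the epoch with the best mean validation Jaccard;
non-finite losses abort with a diagnostic.

## Preprocessing and augmentation

Standardization: resize to 299×299 (bilinear) → grayscale (luminance
weights for RGB, identity for single-channel) → CLAHE → replicate to
three channels → divide by 255.  CLAHE parameters are unspecified
upstream; the defaults are clip limit 2.0 on the familiar OpenCV-style
scale (mapped to scikit-image's fractional limit as clip/100) with an
8×8 tile grid, both configurable.  Bit-exact CLAHE agreement across
libraries is a non-goal.

Augmentation (labeled pairs only, on the fly each epoch): horizontal and
vertical flips each with probability 1/2, rotation with magnitude
U(0°, 10°) and random sign (bilinear for the image, nearest-neighbour
for the mask so labels stay binary, zero fill), and a 10% zoom-in
(center-crop to 90% of each side, resize back) with probability 1/2.
One sampled transform hits image and mask jointly.  Note the zoom-in
necessarily scales mask areas by (1/0.9)² ≈ 1.235; flips and ≤10°
rotations preserve foreground counts to within a few percent.

## Mask post-processing and the CTR head

Probability maps are thresholded at 0.5; connected components smaller
than 0.1% of the image area are discarded; the heart keeps its largest
component, the lungs the union of their two largest.  Bounding boxes use
0-based inclusive indices (width = x_max − x_min + 1).  The thoracic
diameter is the width of the box around the lung-field union.  An image
whose post-processed heart or lungs mask is empty is reported as
*indeterminate* with a nonzero exit count rather than silently
classified.  All of this post-processing is package-defined (the
upstream description stops at "bounding boxes"); every constant is
configurable.

## Evaluation metrics

Segmentation: Jaccard index, with both-empty defined as 1.  Detection:
confusion counts with cardiomegaly positive, sensitivity, specificity,
G-Mean = √(Sens·Spec), accuracy, and ROC AUC.  Reported AUC defaults to
the hard-predictor form (Sens + Spec)/2 — the two-point trapezoid —
because the published per-dataset AUCs equal that expression on every
dataset, implying the AUC was computed from hard calls; a rank-based AUC
over continuous CTR scores (midrank ties) is also available.  Reports
round to two decimals, half away from zero.

## Synthetic phantoms

The phantom generator renders what the pipeline actually measures: two
dark elliptical lung fields on a brighter body background, a bright
cardiac ellipse whose horizontal pixel extent is exactly
round(target_ctr × lung-union extent) (sub-pixel center placement makes
the width exact, so mask-derived CTR matches the target within
2/image_size), an optional vertical intensity gradient, optional
rib-like bands (off by default), and additive Gaussian noise.  Masks are
a deterministic function of the geometry; noise touches only the image.
Identical spec + seed gives bit-identical output.

Dataset generation jitters lung/heart geometry a few percent per sample,
draws target CTRs from a configurable law (default U(0.35, 0.75), which
straddles the π = 0.50 threshold so both classes appear), and writes
8-bit PNGs with a manifest CSV; labeled rows carry mask paths, the true
CTR, and the thresholded label, unlabeled rows leave those fields empty.
Default rendering noise is σ = 0.03 with gradient amplitude 0.10 —
visible texture without burying the anatomy.

What phantoms do *not* emulate: ribs-over-lung texture (unless enabled),
occlusion conventions (the lung masks include the heart-overlapped
region), anatomical shape variability, pathology other than heart width,
and acquisition artefacts.  Passing desk-scale tests therefore
demonstrates that the machinery — losses, gradient routing, batch
planning, geometry — behaves as specified, not that clinical-grade
Jaccard scores are reachable; those require the real datasets and
GPU-scale training, which are out of scope here.

## Desk-scale choices

CPU-scale test and reproduction runs use 64-pixel phantoms with a
reduced network (base 8 filters, depth 3, one block per stage, CBAM on),
batch size 8, and batch-norm momentum 0.9; learning rate and ramp length
keep their reference values.  The lower momentum matters because these
runs take only a few hundred optimisation steps, and with momentum 0.99
the eval-mode running statistics would still be far from the batch
statistics when validation Jaccard is measured.  The full-width
architecture (depth 5, 16→256 filters, three blocks per stage) is
constructed and shape-verified at the 299 input in the tests without
being trained.

The reproduction script (`scripts/acceptance.py`) trains supervised
lung-field models on 40 noiseless phantoms (30 epochs) and runs the
supervised-vs-semi-supervised heart comparison on 10 labeled + 200
unlabeled noisy phantoms (25 epochs), median over 3 seeds — a
desk-scale analogue of the published supervised/semi-supervised
contrast: with scarce labels the consistency term gives the encoder a
large additional training signal, and the semi-supervised heart model
beats the supervised baseline by a wide Jaccard margin.

## Numerical details and edge cases

* BCE probabilities are clipped at 1e-7; Dice smoothing ε = 1e-6.
* F-Drop on a constant latent (min–max normalisation undefined) defines
  the normalised mean as all-zero, so everything is dropped.
* Max-pool backward routes gradient to the first maximum; CBAM max
  branches route to the argmax element.
* `same` transposed-convolution output cropping removes the trailing
  row/column (Keras convention).
* Empty masks raise typed errors (`EmptyMaskError`) that the pipeline
  converts to indeterminate rows; degenerate bounding boxes are
  constructor errors.
* Determinism: every stochastic component draws from an explicit
  `numpy.random.Generator`; fixed seeds reproduce training histories
  bit-for-bit on a given platform (single-threaded BLAS nondeterminism
  aside, which we have not observed at these sizes).

## Known limitations

* The numpy engine is single-threaded-CPU oriented; the reference
  299-pixel, 100-epoch training regime is out of reach with it and is
  not attempted.
* Phantom realism is deliberately minimal (see above).
* CLAHE output differs slightly from OpenCV's implementation.
* Stratified validation splitting guarantees the overall 20% count
  exactly; per-class counts can drift by one for tiny classes.
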