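# Methods

This note records the models, the free parameters and their defaults, the
numerical choices, and what the synthetic data do and do not establish.

## Contrast enhancement

The chain operates on float images in [0, 1] (8-bit files are scaled on
read/write; this avoids integer overflow in the subtractive fusion).
Stages: per-channel denoising → white top-hat / black bottom-hat →
`clip(φ_top + φ_bot − φ, 0, 1)` → dark-channel-prior dehazing → final
fusion `clip(φ_hz·(φ_fused·φ_top) + φ_hz, 0, 1)`.

* **Denoiser** — pluggable: `identity`, 3×3 `median` (default), or
  non-local means. The median suppresses specular "bubble" speckle
  without a learned model.
* **Structuring element** — disk, radius 5 at 256×256 (configurable).
  This is the vessel/bubble scale; much larger radii flatten the lesion
  rim response.
* **Dehazer** — dark channel prior: patch 15, veil weight ω = 0.95,
  transmission floor t₀ = 0.1, atmospheric light from the brightest 0.1 %
  of dark-channel pixels. The transmission floor guarantees finite output
  for degenerate (all-white) inputs.
* The subtractive fusion can go negative and the final fusion can exceed
  one; both are clamped so every stage output is a valid image. A flag
  switches the subtraction reference from the original frame to the
  denoised one.

Note the enhanced output is a *structure map*: flat interior regions are
removed by the hat transforms, so the image is sparse and dark with
bright responses at small-scale structure. This is what the fusion
equations produce; it is deliberately not a photographic "improved"
frame.

## Saliency segmentation

A 14-layer CNN — conv(3×3, stride 2)–BN–ReLU–maxpool(2×2, stride 2),
repeated with a third conv block, then average pool, FC, softmax; filter
widths 8/16/32 — is trained to classify frames with SGD at the study
settings (lr 0.05, momentum 0.6, batch 32, dropout 0.5, 100 epochs).
Input sides must be divisible by 32 (the product of the five stride-2
stages).

* **Training input.** The CNN trains on the *original* frames. Training
  it on the enhanced structure maps proved unreliable: on some seeds SGD
  plateaus near chance and the feature maps carry no lesion signal,
  because the hat transforms delete the flat lesion interior that carries
  the class color. The enhanced image instead enters the saliency path
  through the additive refinement below — the point in the design where
  enhancement and saliency are coupled.
* **Map construction.** The second convolution's response maps on a frame
  are each folded to the absolute deviation from their own median
  (different filters respond to the same structure with opposite sign;
  folding makes them agree), min–max normalized, scored by spatial
  variance, and the top-k (default: half the filters) averaged, upsampled
  bilinearly, and renormalized. A literal weights-visualization mode is
  not meaningful for 3×3 kernels; activations are the standard deep
  saliency reading.
* **Refinement and threshold.** `O_map` plus the channel mean of the
  enhanced frame, renormalized; binarized at the map's arithmetic mean
  with ties to foreground; morphological closing (disk 3) plus hole
  filling. The mean threshold intentionally over-segments (~30 % of the
  frame); the contour stage below tightens it.
* **Localization.** Per connected component (≥ `min_area`, default 64 px)
  a morphological Chan–Vese contour (50 iterations) runs in a 10 px-padded
  window, initialized from the component. The contour bi-partitions the
  window by intensity; both phases are decomposed into connected pieces
  and the lesion piece is the one holding the most *saliency mass above
  the window mean*. This score was chosen after failure analysis: a tiny
  specular highlight wins a mean-saliency contest, a huge background
  piece wins a total-saliency contest, and a whole-window piece scores
  exactly zero excess mass. Regions whose score falls below 25 % of the
  best region's are dropped from the segmentation union as spurious.
  Boxes are 0-based and half-open.

Convolutions use edge (replicate) padding rather than zero padding, so a
constant image produces constant feature maps and the saliency of a
structureless frame is identically zero; the backward pass folds the
pad-region gradient onto the edge pixels.

After SGD, batch-norm running statistics are re-estimated in one pass
over the training set with the final weights. With few large steps the
exponentially averaged statistics lag the weights badly enough to cost
tens of accuracy points at evaluation; the recalibration pins them.

## Backbone features and Bayesian optimization

Two architectures sit behind one interface: a NumPy MobileNet-V2
(standard inverted-residual layout, 1280-dim global-average-pool
embedding; inference only, He-initialized from a seed, batch norms set by
one seeded calibration pass and then frozen) and a trainable `tiny_cnn`
(three conv blocks, configurable embedding width, default 64, input
64×64). "Replacing the last layers" means dropout(0.2) + linear sized to
the task's classes. For `mobilenet_v2` fine-tuning trains the head on the
frozen trunk's features; `tiny_cnn` trains end-to-end. No pretrained
weights are downloaded; random-init embeddings suffice for every
structural contract and the tiny network for every behavioral one.

The SGD hyperparameters live in the box lr ∈ [1e-4, 1], momentum ∈
[0.6, 0.8], L2 ∈ [1e-10, 1e-2]; lr and L2 are searched on a log scale.
The optimizer is a from-scratch GP-EI loop:

* Matérn-5/2 kernel with per-dimension length scales; hyperparameters by
  L-BFGS-B on the marginal likelihood, 4 starts; Cholesky with jitter
  1e-12, escalated ×100 only if the factorization fails.
* Latin-hypercube initial design (default 5), EI maximized over 256
  seeded candidates with local refinement from the best 5; minimization
  convention throughout; non-finite objective values are recorded at a
  penalty one above the worst observation.
* The BO objective for hyperparameter tuning is the validation error
  after a 3-epoch proxy fine-tune from a fresh seeded init (a full
  training per evaluation would dominate the budget without changing the
  ranking at this scale).

## Hybrid whale/hawk feature selection

Agents are continuous vectors in [0, 1]^D; sigmoid transfer and 0.5 cut
give the column mask, with the largest-position dimension forced on if
the mask would be empty. The whale phase (default V = 200 iterations,
population 10) updates each agent by the spiral rule when a uniform draw
P exceeds the *median* of the agent's own position values, otherwise by
encircling the best (mean |W| < 1) or a random agent (mean |W| ≥ 1), with
W = 2cd − c, U = 2d′ and c = 2 − 2v/V. W and U are per-dimension vectors
with independent draws; a scalar-W variant was measurably worse — with a
sparse incumbent every dimension contracts with the same sign and the
population collapses onto the empty-mask corner. Spiral constant a = 1.
The best (error, subset size) pair is kept elitistically, so the
best-fitness history is monotone and ties at equal error prefer fewer
columns.

The hawk refinement (default 50 iterations) runs the two-branch perch
exploration — toward a random agent when Q ≥ mean(position), else the
rabbit-minus-population-mean move — over the column subset the whale
phase selected (a flag switches to the full matrix warm-started from the
mask). It can never return a mask worse than its start.

**Fitness** is the error rate of an ELM (100 hidden units, ridge 1e-6)
on the masked columns, estimated by seeded stratified 4-fold
cross-validation (mean over folds). A single fixed holdout was the
original design but proved unusable: with 60 validation samples the
error resolution is 1.7 %, the wrapper overfits the one split, and the
planted-feature recovery rate stays below its floor no matter how the
ELM is configured; the CV estimate has per-sample resolution over the
whole table and restores recovery. `fitness_folds=1` reinstates the
holdout. Realized subset sizes are data-dependent and reported, never
enforced.

## Extreme learning machine

Single hidden layer, sigmoid activation, input weights and biases drawn
U(−1, 1) under a seed, output weights by the ridge-regularized normal
equations against one-hot targets; prediction is the class-score argmax.
Defaults: 500 hidden units, ridge 1e-6. Features are standardized with
training statistics before the random projection so arbitrarily scaled
embeddings do not saturate the sigmoid. Multi-class is one-hot
regression + argmax.

## Synthetic data

Frames (default 96×96): mucosa-toned base (0.70, 0.42, 0.38) with
smoothed value-noise texture (amplitude 0.035, correlation length 6 px),
one elliptical lesion per frame (semi-axes 12–20 px) whose color shift
depends on the class (dark-red ulcer-like vs bright-yellow polyp-like at
contrast 0.30), three specular bubble discs (placed off-lesion so the
ground-truth contrast is preserved), and a 10 % additive white veil. The
generator self-checks that the lesion remains visible and returns the
exact ellipse masks. Tables: k informative Gaussian columns with
class-conditional means separated by the effect size (default 2 sd),
the rest standard normal.

What the generator does *not* emulate: realistic mucosa geometry,
specular anisotropy, motion blur, compression artifacts, multi-lesion
interactions, or class imbalance. Passing tests therefore establish that
each stage does what its equations say and that the chain recovers
planted structure under controlled conditions — not clinical
performance.

## Study sizes and defaults used by the tests

The test-suite and the acceptance script run the pipeline on 60 frames
(50:50 stratified split), the selector at population 10 with V = 50 on
n = 200, D = 50, k = 5 tables over 10 seeds (V = 200 remains the library
default), segmentation IoU over 10 frames against generator masks, and
BO at a 4 + 10 budget on a 1-D quadratic. These sizes were chosen as the
smallest at which each property is stable across seeds.

## Known limitations

* The saliency map's spatial resolution is bounded by the second
  convolution's grid (1/8 of the input side); the Chan–Vese stage is
  responsible for boundary accuracy.
* The MobileNet-V2 trunk is inference-only; full-network fine-tuning is
  available only for `tiny_cnn`.
* The 10-fold split mode re-trains every stage per fold and is
  correspondingly slow; the 50:50 holdout is the default.
* The whale/hawk search is a stochastic wrapper: at V = 50 on D = 50 it
  examines ~10³ of 2⁵⁰ masks, so the recovered subset varies with seed
  even when the best-fitness history is monotone.
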