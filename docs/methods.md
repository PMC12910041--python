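# Methods

## The protocol

`litepath` implements a controlled comparison of compact CNNs for
three-class histopathology classification. Every architecture in the family
is built from one canonical block — 3×3 same-padded convolution, batch
normalization, ReLU, 2×2 max pooling — repeated with a variant-specific
filter progression, then global average pooling, a 256-unit ReLU dense
layer, dropout at rate 0.4, and a 3-way softmax. The four built-ins are

| variant | blocks | filters | exact trainable params (any input) |
|---|---|---|---|
| Lite-V0 | 3 | 16–32–64 | 41,219 |
| Lite-V1 | 4 | 32–64–128–128 | 275,331 |
| Lite-V2 | 5 | 32–64–128–256–256 | 1,046,531 |
| Lite-V4 | 6 | 32–64–128–256–512–512 | 4,063,491 |

The family deliberately has no "V3". Parameter counts are computed exactly
(`c_out·(9·c_in + 1)` per convolution, `2·c_out` trainable per batch norm,
`d_out·(d_in + 1)` per dense layer); capacity is strictly increasing
V0 < V1 < V2 < V4, which is the design axis of the comparison. Nominal
"approximate" parameter figures sometimes quoted for such families are
order-of-magnitude summaries; nothing in this package depends on them.
Because each block halves the spatial side, a model is buildable only when
the input side is divisible by 2^blocks; this is checked at build time (the
declarative config table itself is valid at any nominal size, since the
six-block variant cannot divide the conventional 224-pixel input).

All variants train under one fixed regime: Adam at learning rate 1e-3,
batch size 32, class-weighted softmax cross-entropy, at most 25 epochs,
random seed 42 by default. Selection is driven by validation macro-F1
computed over the full, unaugmented validation split at each epoch end:
an epoch *improves* iff its macro-F1 strictly exceeds the best so far by
more than the tolerance (default 1e-4); improvement re-saves the checkpoint
and resets a counter; six consecutive non-improving epochs stop training.
The returned model always carries the best-checkpoint weights. Winner
selection across variants ranks by best validation macro-F1, ties going to
the smaller model, and the winner is evaluated on the held-out test split
exactly once; the experiment runner enforces this with a guard object that
raises on any test-set access before selection and records the access order
in the run manifest.

## Statistics

Two classifiers evaluated on the same test samples give a 2×2 concordance
table; only the discordant counts *b* (reference right, competitor wrong)
and *c* (converse) inform a difference in error rates. Under H₀: b = c,
b ~ Binomial(b + c, ½), and the exact two-sided p-value is twice the smaller
tail, clamped at one. The tail is summed with Python integer arithmetic
(binomial coefficients over 2^n), so no normal approximation or floating
cancellation enters; for the symmetric null this doubling rule coincides
with the minimum-likelihood two-sided binomial test, which the test suite
verifies against `scipy.stats.binomtest` for all b + c ≤ 60. A
continuity-corrected χ² version is provided as a labeled alternative but is
never the default. Family-wise error over several comparisons is controlled
by Holm–Bonferroni applied to the *unrounded* p-values (rounding before
adjustment changes the third significant figure of small products). The
multi-seed stability summary reports mean ± sample standard deviation
(n−1 denominator) of validation/test accuracy and macro-F1.

Metric conventions: the confusion matrix stores true class in rows and
predicted class in columns; precision/recall/F1 use the zero-division → 0
convention; macro aggregates are unweighted class means, weighted aggregates
are support-weighted; predicted labels are the softmax argmax with
lowest-index tie-breaking. Metrics are stored at full precision and
displayed at 4 decimals. Note that a macro average recomputed from
*rounded* per-class F1 values can disagree with a separately rounded macro
figure in the last printed digit; this package always computes the true
mean.

## The synthetic generator

The generator emulates the *structure* of a balanced three-class H&E
benchmark — RGB images, one subdirectory per class, balanced splits — not
the pixel statistics of real tissue. Each image is an eosin-pink background
(per-image hue jitter scaled by `palette_jitter`) carrying
hematoxylin-purple texture primitives. A primitive is an anisotropic
Gaussian spot with a continuous ring parameter, so all classes live on one
parameter manifold with three coordinates: density (expected primitives per
image), elongation, and ringness (solid blob → annulus). Class offsets on
these coordinates are scaled by `separability ∈ [0, 1]`: at 0 the three
classes draw from *identical* distributions (no classifier can beat chance;
the suite checks a two-sample KS test on per-class mean intensities and the
exact binomial 99% chance band on test accuracy), while at 0.9 class 0
shows sparse round blobs, class 1 medium-density annuli and class 2 dense
elongated streaks. Defaults: 64×64 pixels, separability 0.9, pixel noise
sd 0.05, palette jitter 0.3. Offsets were chosen once so that the
separability knob spans chance-level to near-perfectly-learnable for the
smallest variant; the learnability test confirms mean test macro-F1 is
non-decreasing across separability 0.2 < 0.5 < 0.9.

What passing tests therefore show: the training loop, callback, selection
and statistics behave correctly on a controllable benchmark. What they do
not show: performance on real histopathology — the generator has no nuclear
morphology, stain variation, scanner artifacts or within-class
heterogeneity, and no claim of biological fidelity is made.

Generation is fully deterministic: one PCG64 stream per (seed, split,
class), no time-based entropy; identical configs give byte-identical
arrays, and PNG serialization is 8-bit (round-trips are exact to 1/255).

## Numerical choices

* **Engine.** NHWC float32 throughout; convolutions via im2col +
  BLAS matmul; the input gradient is the correlation of the upstream
  gradient with the 180°-flipped kernel (exact for stride-1 same padding).
  Max-pool ties break to the first position. The backward pass is verified
  against central finite differences in the suite.
* **Initialization.** Glorot-uniform, drawn from a seeded generator; two
  builds with the same seed give identical initial losses.
* **Batch normalization.** Epsilon 1e-3; running-statistics momentum 0.9.
  The momentum matters at desk scale: with ~20 optimizer steps per epoch, a
  0.99 momentum leaves the inference-time running estimates dominated by
  their initialization for many epochs, so validation predictions sit at
  chance while training accuracy is high. 0.9 converges within the first
  epochs at the problem sizes this package targets and is recorded in the
  RunLog environment metadata.
* **Loss.** Mean over samples of `w_y · (−ln p_y)` with probabilities
  clamped at 1e-12; class weights are per-sample loss multipliers (not
  resampling). Validation/test losses are unweighted.
* **Augmentation** (train split only; calling it on other splits raises a
  contract violation): horizontal flip with probability ½ applied by array
  slicing (an exact involution), then rotation U(−5°, +5°) and zoom
  U(0.95, 1.05) composed into a single bilinear warp with edge reflection —
  one interpolation, no black borders. Degrees are the canonical rotation
  unit; a `rotation_as_fraction` flag reinterprets the magnitude as a
  fraction of a full turn (0.05 turn = 18°) for compatibility with
  framework-style configs.
* **Splitting.** Stratified with per-class rounding error ≤ 1 per split;
  a class smaller than the number of non-empty splits is rejected.
* **Degenerate inputs.** Empty validation set (macro-F1 undefined), b + c =
  0 (McNemar undefined), all-zero confusion matrix, empty class, infeasible
  concordance counts: all raise named errors rather than returning NaN.
* **Reduce-on-plateau** (factor 0.1, own patience, monitoring validation
  macro-F1) is implemented but off by default.

## Problem sizes

The package's reference conditions are deliberately desk-scale: the
benchmark experiment trains the smallest variant on 200/60/60 images per
class at 64×64 (about a minute on one CPU core); the chance-floor control
uses 60/30/30 at 32×32; the learnability sweep uses 100/30/30 at 32×32 over
three seeds; protocol-reproducibility checks run two variants on 12/6/6 at
16×16. The full-scale split sizes (3,500/500/1,000 per class at 224×224,
giving 329 steps per epoch at batch 32) remain reachable through the same
configs, but reproducing results at that scale requires the corresponding
real dataset and far more compute than the bundled benchmark targets.

## Known limitations

* The numpy engine is single-process and CPU-only; it is not intended for
  224×224 training at tens of thousands of images.
* Stride/pool geometry is fixed to the canonical block (stride-1 3×3 conv,
  2×2 pool); inputs must be divisible by 2^blocks — odd-size pooling is not
  implemented.
* Epoch-end validation uses the current (final-batch) weights of that
  epoch; no weight averaging.
* Bit-reproducibility is promised only for single-threaded CPU execution
  with identical library versions.
* No stain normalization, whole-slide tiling, ROC/AUC, calibration or
  saliency analysis; the statistics are limited to McNemar + Holm and
  mean ± sd summaries.
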