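# Methods

## The problem

Unsupervised anomaly segmentation normally assumes an anomaly-free
training set: a generative model is fit to "normal" images, and at test
time pixels that the model cannot explain are flagged.  In many settings —
oncological PET being the motivating one — no such clean training set
exists: most or all available scans contain lesions.  This package
implements an iterative, self-supervised training scheme that makes the
generative approach robust to heavily contaminated training data by
repeatedly detecting suspected anomalies in the training set itself and
masking them out of the next training round.

## Pipeline

1. **Discrete tokenization (VQ-VAE).**  An encoder maps an image
   `x ∈ [0,1]^{H×W}` to a latent grid `Z ∈ R^{h×w×n_z}` (downsampling
   factor `2^n_stages`, default 4).  Each latent site is replaced by its
   nearest codebook vector `e_k` (Euclidean distance; ties go to the
   lowest index), giving the quantized latent `Z_q` and the integer token
   grid `Z_iq`.  The decoder mirrors the encoder and carries dropout, so
   decoding the same `Z_q` repeatedly with dropout active produces a
   *distribution* of plausible reconstructions.  Training uses the
   standard recipe: `L = ||x − x̂||² + ||sg(Z) − Z_q||² + β||Z − sg(Z_q)||²`
   with a straight-through gradient through the quantizer (β = 0.25).
   The networks are patchify (space-to-depth) + linear + ReLU stages —
   kernel-equals-stride convolutions — implemented in NumPy with
   hand-derived, finite-difference-verified gradients.

2. **Autoregressive prior (transformer).**  Token grids are rasterized
   row-major into sequences `s` of length `l = h·w`.  A decoder-only
   transformer (pre-LayerNorm, learned positional embeddings, GELU MLPs)
   models `p(s_i | s_{<i})`, anchored by a begin-of-sequence token.

3. **Healing and KDE scoring.**  Tokens with `p(s_i) < t` (resampling
   threshold, default `t = 0.005`) are flagged and redrawn from the
   model's next-token distribution, left to right, conditioning on
   already-healed earlier positions.  With `n_resamples` healed sequences,
   each decoded `n_decodes` times with dropout (defaults 60 × 5 = 300),
   every pixel acquires a sample of "healed" intensities `x_1..x_n`.  A
   Gaussian KDE with Silverman bandwidth
   `h = (4σ̂⁵/3n)^{1/5} + ε` (σ̂ the sample standard deviation, ddof = 1,
   defined as 0 for constant samples; ε = 0.05 on the [0,1] intensity
   scale) is fit per pixel, and the anomaly score is the log density of
   the *observed* intensity: `L = log( (1/nh) Σ K((x₀−x_i)/h) )`.
   Pixels with density below 0.005 (`L < log 0.005`) are segmented as
   anomalous.  A `literal_sum` flag drops the 1/n factor inside the log
   (a constant shift of `log n` at fixed stack size, so segmentations at
   matched thresholds are unchanged).

4. **Iterative latent token masking.**  The quantizer is trained once on
   the contaminated data and frozen.  The prior is trained iteratively:
   iteration 0 with no masks; each iteration then scores every training
   image, thresholds the KDE map, max-pools the segmentation down to the
   latent grid (any flagged pixel flags its token), and the next training
   round excludes those tokens.  The resampling threshold decays as
   `t_m = t₀(1−decay)^m` (decay 12.5%); the loop stops when the total
   masked-token count changes by ≤ 1% between iterations, or at
   `max_iterations`.  The prior trained with masks is, in robust-statistics
   terms, an M-estimator of the inlier token distribution: as anomalous
   tokens are removed from the objective, the fitted parameters approach
   those of a model trained on inliers alone.

## The token-masking contract

Removing a suspected token's influence must be *exact*: a later scoring
pass should behave as if the token had never been seen.  Two mechanisms
together guarantee this bit-for-bit:

* the masked token's input embedding is replaced by a dedicated learned
  MASK embedding, so its value never enters the network;
* masked positions are excluded as attention keys for every query (their
  pre-softmax scores are −∞, which is exactly 0 after softmax), so even
  their positional presence is invisible to other positions.

Predictions *at* masked positions are still computed — from the unmasked
context — so masked tokens can be resampled.  The loss averages the
cross-entropy over unmasked target positions only; with all-zero masks it
is exactly the ordinary autoregressive objective.  Masking a full query
row as well would make the softmax at that row undefined, which is why
the row side of attention is left intact.

One consequence is worth naming: the position immediately after a masked
token starts its residual stream from the MASK embedding, so a model
trained with masks can learn that "a mask is present here" predicts what
follows.  The scoring rule below is designed so this cannot silently
un-flag anomalies.

## Scoring the training set inside the loop

When the loop re-scores the training data at iteration m, a token is
flagged for resampling if it is improbable under *either* of two
conditioning views: (a) the plain context, and (b) the context with the
previous iteration's masked tokens excluded.  View (b) exposes anomalous
continuations whose visible anomalous neighbours would otherwise make
them look likely; view (a) is immune to the learned mask-presence cue
described above.  Healing itself always conditions on the healed prefix,
so a healed anomaly onset steers later flagged positions toward coherent
normal continuations, keeping the reconstruction stack concentrated and
the KDE sharp.  Both behaviours are config-exposed
(`LoopConfig.mask_context_scoring`).

## Common random numbers across iterations

Retraining is from scratch each iteration but reuses one derived
initialization/shuffle seed, and scoring reuses one healing/decode seed.
Differences between consecutive iterations are then attributable to the
masks alone rather than to fresh training noise — a paired design that
also makes the masked-token convergence rule meaningful at desk scale.
(A warm-start mode, `fine_tune=True` with `fine_tune_epochs`, continues
the previous iteration's parameters instead; the desk profile uses it to
keep runs within minutes.)

## The synthetic data generator

The generator emulates the statistical setting of contaminated-training
anomaly segmentation: homogeneous textured normal images and localized
blob anomalies of shifted intensity, at an exactly controlled
contamination ratio with exact ground-truth masks.

* **Normal images** are white Gaussian noise convolved with a Gaussian
  kernel (`filter_sigma`, default 4.0 pixels) and min-max rescaled to
  [0, 1].  The smoothing scale is deliberately *larger* than the
  tokenizer's 4×4 patch size: normal texture is then predictable from
  neighbouring context, while anomalies are not — the ordering that
  defines the anomaly-detection setting being emulated (structured
  healthy anatomy, unpredictable lesions).  With a correlation length
  below the patch size, normal tokens would be as surprising as anomalous
  ones and no contextual detector could separate them.
* **Anomalies** are 1–3 additive elliptical blobs (radius 2–5 px, linear
  soft edge of ±1.5 px) with an intensity shift of 0.3–0.6.  One shift
  direction per image ("auto": brighten dark images, darken bright ones)
  avoids head-room clipping and cancellation between blobs.  The
  ground-truth mask is the support where a blob's additive field exceeds
  half its peak, i.e. the nominal-radius ellipse.  A post-hoc check
  rescales the field (at most 4 times) until the mean contrast between
  the blob interior and the surrounding unmodified texture reaches
  `min_contrast` (default 0.15).
* **What it does not emulate:** PET physics, 3-D anatomy, non-local
  anomaly structure, intensity calibration across subjects, or the
  appearance of industrial defect categories.  Passing tests show the
  *method* behaves as designed under its stated assumptions, not that it
  reaches any particular performance on real scanner data.

## Desk-scale study conditions

The reference experiment (`iltm.experiments`) uses 200 training images of
32×32 (8×8 latent grid, 64-token sequences, K = 64 codes), 50 held-out
images, 50% training contamination, three loop iterations, and a reduced
healing budget of 6 resamples × 2 decodes.  The quantizer trains for 40
epochs (dead-code revival on — uniform-initialized codebooks at K = 64
otherwise collapse on 200 images); the prior trains 16 epochs on the 8
dihedral transforms of each token grid (augmentation closes an otherwise
severe train/held-out generalization gap at n = 200) and warm-starts 8
epochs per masking iteration.  A full run takes a few minutes on one CPU
core; problem sizes were chosen so the entire study (three seeds plus a
clean-data control) completes in tens of minutes.

## Numerical choices

* Nearest-neighbour quantization computes explicit squared differences
  (not the expanded dot-product form) so small-integer ties break
  exactly, deterministically, toward the lowest codebook index.
* Attention masking uses −1e30, whose exponential underflows to exactly
  0 — masked contributions are bit-exact zeros, not merely small.
* Reported token likelihoods are floored at 1e-12; KDE densities at
  1e-300 before the log, keeping scores finite even for extreme outliers.
* σ̂ of an exactly-constant pixel sample is set to 0 directly, so the
  degenerate bandwidth is exactly ε.
* The transformer supports float32 (`TransformerConfig.dtype`) — the
  masking contract is exact in either precision; float64 is the default.
* Evaluation: AUROC and best-DICE pool pixels across the test set;
  best-DICE searches every distinct score when there are ≤ 10,000,
  otherwise a 1000-point quantile grid.  AUPRO integrates mean
  per-connected-region overlap against pooled false-positive rate up to
  `fpr_limit` (default 0.3, the industrial-benchmark convention) with
  trapezoidal interpolation, normalized by the limit.

## Known limitations

* The desk-scale profile detects roughly the anomaly onsets in raster
  order plus cells flagged by the masked-context view; blob interiors
  that remain predictable from visible blob context are missed by the
  token stage, bounding pixel AUROC well below what lesion-scale data
  with a larger token grid would allow.
* The effect of three masking iterations at these problem sizes is small
  relative to scoring stochasticity; the study therefore pairs models on
  identical healing/decode randomness when comparing them.
* Within the first retraining round, the prior's continued fit to the
  anomalous tokens that remain visible (mask recall is ~0.24 at precision
  ~0.56) can sharpen their predictability slightly faster than the masks
  remove their influence: the recall of the token masks against ground
  truth typically dips by a percent or two (relative) at iteration 1
  before recovering.  Held-out detection of the final model still
  improves consistently; only the strict per-iteration monotonicity of
  mask recall fails at this scale.
* The 12.5% threshold decay is designed for longer runs; over three
  iterations it mainly trades a few detections for fewer false positives.
* 3-D volumes are out of scope; the code handles 2-D grayscale images.
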