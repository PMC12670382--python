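# Methods notes

## The procedure in brief

The package operationalizes one hypothesis — aesthetic pleasure is
inversely related to the metabolic cost of visual encoding — with two cost
proxies that share a statistical core.

In the DNN arm, a feedforward network is split into blocks, one per weight
layer; the block's captured tensor is the last one produced before the next
weight layer runs (so ReLU and pooling outputs are included, and a reshape
changes nothing). Costs per block are `active_count` (elements strictly
greater than zero) or `activation_sum` (sum of positive parts). Totals per
image are row sums across blocks. The observed total-cost/rating Spearman
correlation is located within the distribution of the same statistic over N
randomly initialized copies of the architecture (seeds 0..N−1), giving the
one-tailed ensemble p = #{ρ_null < ρ_obs}/N with strict inequality and no
small-sample correction (a (count+1)/(N+1) variant is available behind a
flag).

In the fMRI arm, the cost of an image in an ROI is the *signed* sum of
single-trial voxel betas (no rectification — betas are percent signal
change and may legitimately be negative), averaged over repeated
presentations and then over the subjects contributing that image.
Correlations with the rating outcome are computed per ROI with Fisher-z
confidence intervals; a cross-ROI OLS predicts ratings from all ROI costs
under the same k-fold machinery as the DNN arm.

## Assumptions and conventions

* **"Active" means strictly > 0.** Post-ReLU tensors are non-negative, so
  "nonzero" and "> 0" coincide everywhere except the final FC layer, which
  has no ReLU; there the same positive-part rule is applied to the logits
  for a uniform metric. This is a deliberate convention: counting negative
  logits as active would make the last block's count nearly constant.
* **Preprocessing.** Inputs are bilinearly resized to 375 × 375 (the
  resolution at which ratings are collected), scaled to [0, 1]. Channel
  normalization is identity for untrained networks and the ImageNet
  mean/SD constants when trained weights expecting them are loaded; the
  choice is explicit in the call signature rather than hidden.
* **Non-224 inputs.** An adaptive average-pooling stage maps any spatial
  size onto the 7 × 7 grid the VGG-19 classifier expects, so the FC
  dimensions are independent of input resolution.
* **Initialization.** Untrained networks draw weights and biases from
  U(±1/√fan_in) under a per-model seed — the standard fan-in-scaled
  uniform default for ReLU conv nets — so "seed s" fully determines a
  model.
* **z-scoring.** Participant z-scores use the sample SD (n−1).
  Zero-variance raters are dropped with a warning rather than imputed at
  z = 0: a constant rater carries no ordinal information, and imputing
  zeros would pull image means toward 0 asymmetrically.
* **k-fold contract.** Shuffled k-fold = permute indices once under the
  configured seed, slice into k contiguous near-equal folds (this is also
  what scikit-learn's shuffled KFold does; pinning the construction makes
  the partition reproducible across languages). Defaults: k = 10,
  shuffle on, seed 0.
* **Explained variance.** `full_r2` is the in-sample R² of the all-data
  OLS fit (the canonical single number). The cumulative curve is the
  fold-averaged *training* R² as predictors enter in depth order, so its
  final value equals the fold-averaged full-model training R²
  (`cv_train_r2`), not `full_r2`; both are reported.
* **Rank-deficient designs** (e.g. a constant or duplicated cost column)
  fall back to the least-norm OLS solution with a warning instead of
  failing: out-of-fold predictions remain well-defined even when
  individual coefficients are not.
* **Gini on signed betas.** The Gini formula requires non-negative input;
  voxel betas do not oblige. Default policy is absolute values, with
  positive-part clamping as the alternative; the choice is an explicit
  argument (and a CLI flag) because it is a genuine modelling decision.
* **Repeats.** Averaging over repeated presentations is the default; a
  first-presentation-only mode exists because repetition itself shifts
  aesthetic responses.
* **Ties** use average ranks throughout; per-layer tests report raw p and
  Benjamini–Hochberg adjusted p within a network.
* **Multiple subjects.** Group-level series average over the subjects
  contributing each image; coverage imbalances are logged.

## The synthetic generators

The generators exist so that the downstream analyses have a ground truth:

* **Images** are 1/f^α amplitude-spectrum noise with random phases,
  centred at mid-grey, scaled to a target RMS contrast (default 0.15 —
  low enough that clipping does not bias the spectrum), 8-bit quantized.
  They reproduce the second-order statistics of natural images and nothing
  else: no objects, no scenes, no semantic content.
* **Rating tables** use a greedy least-covered-first assignment, so
  per-image rater counts differ by at most 1 (matching a balanced crowd
  design, ~50 raters/image at scale); ratings are uniform draws or a
  discretized noisy readout of a latent appeal vector with per-participant
  leniency biases.
* **The cost-rating link** plants `rating = sign(ρ_target)·standardize(cost)
  + noise`, with the noise SD solved by bisection on seeded pilot draws
  (200-sample pilots, 40 replicates per iterate) so the realized Spearman
  matches the target. Calibration error is dominated by the n of the final
  draw (SD ≈ 1/√n), hence the ±0.08 Monte-Carlo tolerance at n = 500.
* **Voxel betas** spread a rank-monotone per-image signal across voxels by
  fixed non-negative loadings, add constant per-voxel baselines (which
  cancel in image-level correlations) and i.i.d. noise; the signal
  amplitude is solved by bisection against the *aggregate* noise level
  σ·√(V/(R·S)), so the planted correlation refers to the fully aggregated
  series, which is what the pipeline estimates. Defaults (4 subjects,
  8 ROIs, 2 repeats) mirror a small multi-subject single-trial design.

What passing tests on these data do **not** show: that real images, real
raters, or real BOLD responses behave this way. The generators contain no
semantic content, no spatial voxel correlations, no hemodynamics, no
session/run structure, and rater noise is i.i.d. Gaussian. Recovery tests
validate the *estimators*, not the empirical claim.

* **The toy classifier** is a 3-conv + 1-fc net trained on a texture-
  orientation task (oriented gratings in 1/f noise, 24 px). It exists so a
  *trained* network can be contrasted with untrained twins through the
  identical cost pipeline at desk scale; it makes no claim to emulate
  object recognition. 12 epochs of SGD (lr 0.05, momentum 0.9) reach
  well above 2× chance on held-out data in a few seconds.

## Numerical choices

* Forward activations in float32; cost sums accumulate in float64; OLS via
  LAPACK least squares in float64 (coefficient recovery to ~1e-12 on
  well-conditioned designs).
* Bisection tolerances: 30 iterations on a bracketing interval, which is
  far below the Monte-Carlo noise floor of the pilot estimate.
* Spectral slope fitting uses integer radial rings from frequency 2 to
  side/4, avoiding the DC bin and corner anisotropy; at 128 px the fit is
  within ±0.15 of −α.
* Ensemble evaluation streams one model at a time (construct → init →
  evaluate → discard), so a 1,000-member VGG-scale ensemble is bounded by
  a single model's memory.
* Degenerate inputs: constant vectors raise in `spearman_assoc` but are
  *flagged* (not raised) in the column-wise and voxel-wise wrappers, where
  one dead unit should not abort a map.

## Problem sizes

Tests and the acceptance script run everything at desk scale by design:
toy networks (2–6 weight layers), 8–400 images, ensembles of 30–99 seeds,
200-experiment calibration batches. These sizes were chosen as the smallest
at which the Monte-Carlo tolerances above are meaningful. The same code
paths scale to the full setting (19-block VGG-19 at 375 px, 1,000-seed
ensembles, ~5,000 images) without modification; the ensemble streaming
contract and per-image forward passes keep memory flat.

## Known limitations

* No recurrent/transformer architectures; residual nets are supported via
  the identity-skip container, but projection shortcuts must be expressed
  in the trunk.
* No FLOP- or energy-model-based costs; the proxies are activation counts
  and sums only.
* NIfTI support assumes beta and label volumes share grid and orientation;
  no resampling or registration is performed.
* The voxelwise map applies an uncorrected threshold; cluster-extent or
  FDR correction across voxels is out of scope.
* Pretrained VGG-19 weights are not bundled; trained-vs-untrained
  contrasts at full scale require the user to supply weights.
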