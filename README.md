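# neurocost

Tools for testing whether aesthetic pleasure is inversely related to the
metabolic expense of visual processing, using two complementary proxies of
metabolic cost:

* **DNN arm** — layer-wise activation costs of feedforward vision networks
  (VGG-19 or smaller nets), compared against ensembles of seeded,
  randomly initialized copies of the same architecture;
* **fMRI arm** — ROI-summed single-trial BOLD beta estimates (percent
  signal change) in visual regions (V1–V4, PPA, FFA, LOC, OPA).

The package is aimed at computational-neuroscience and empirical-aesthetics
researchers who want a tested, reusable implementation of this analysis
chain, plus synthetic-data generators with *planted* structure so every
stage can be validated end to end without any external downloads.

## The model and statistics

**Outcome.** Raw crowd ratings (1..K enjoyment scale) are z-scored within
each participant, `z = (r − r̄_p) / s_p` (sample SD), and averaged per
image; the per-image mean z is the aesthetic-pleasure outcome.

**Cost proxies.** A feedforward network is partitioned into blocks, one per
weight layer (VGG-19 → 19 blocks: 16 conv + 3 fc), each block spanning that
layer plus the parameter-free functions (ReLU, pooling) before the next
weight layer. For a captured tensor **a**, the per-block cost is either

* `active_count` = #{aᵢ > 0} — each active unit a proxy for a spiking
  neuron, or
* `activation_sum` = Σ max(aᵢ, 0) — weighting active units by intensity.

On the fMRI side the cost of an image in an ROI is the signed sum of the
ROI's voxel betas, averaged over repeated presentations, then over
subjects.

**Association.** Spearman rank correlation (average ranks on ties;
Fisher-z CIs with variance 1.06/(n−3)) between total cost and the outcome.
Against an N-member null ensemble of seed-initialized untrained networks,
the one-tailed nonparametric p is `#{ρ_null < ρ_observed} / N`.
Layer-wise prediction uses shuffled 10-fold cross-validation (indices
permuted once under a seed, sliced into contiguous near-equal folds):
per-fold OLS, pooled out-of-fold predictions, accuracy = Spearman(ŷ, y),
plus a cumulative R² curve as blocks enter in depth order. ROI sparseness
uses the Gini index `G = 2·Σᵢ i·x₍ᵢ₎ / (n·Σx) − (n+1)/n` (x ascending,
1-based ranks).

The network substrate is a compact seeded NumPy inference/training engine
(`neurocost.nn`): im2col convolution, max/adaptive-average pooling, linear
layers, ReLU, with fan-in-scaled uniform initialization and enough backprop
to train the toy classifier used in trained-vs-untrained contrasts.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/03_layer_costs_and_null_ensemble.py` trains a toy
classifier, computes per-block costs on 100 synthetic 1/f images, links
ratings to the total cost with a planted ρ of −0.3, and compares against a
50-seed untrained ensemble:

```
toy classifier held-out accuracy 1.00 (chance 0.25)
cost matrix: 100 images x 4 blocks (['conv', 'conv', 'conv', 'fc'])
total-cost Spearman rho = -0.297 (p = 0.00273) -- images that activate more
units are liked less, as planted
untrained-ensemble null: mean rho -0.183 (sd 0.071); one-tailed ensemble p = 0.060
```

The recovered ρ = −0.297 matches the planted −0.3; the ensemble p is the
fraction of untrained models whose correlation is more negative than the
trained model's (note that untrained networks correlate too — their costs
also track image statistics — which is exactly why the ensemble comparison
is needed). `examples/05_roi_betas_and_sparseness.py` shows the fMRI arm:
with a correlation of −0.4 planted in PPA only, the pipeline reports
`PPA rho = -0.418 [-0.529, -0.292]` while all other ROIs' CIs cover 0.

End-to-end runs are available programmatically
(`neurocost.run_experiment`) or via the thin CLI:

```bash
neurocost run --config cfg.json      # both arms, summary JSON + tables
neurocost synth images --out DIR     # synthetic stimuli / ratings / betas
neurocost dnn-costs --images DIR --out costs.csv --arch vgg19
neurocost fmri-roi --betas b.csv --ratings r.csv --out DIR
```

## Layout

```
src/neurocost/
  nn/            seeded NumPy feedforward engine + architectures
  synthetic.py   planted-structure generators (images, ratings, betas, toy net)
  ratings.py     per-participant z-scoring -> per-image outcome
  activation.py  preprocessing, block partition, cost metrics, null ensembles
  association.py Spearman/CI, ensemble p, k-fold OLS, cumulative R² curve
  fmri.py        ROI aggregation, Gini sparseness, voxelwise maps, NIfTI IO
  workbench.py   config-driven end-to-end runs
  cli.py         thin command-line face
docs/methods.md  modelling assumptions, parameter choices, limitations
examples/        one narrative script per capability
```
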