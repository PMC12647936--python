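# Methods

This note documents the models, the synthetic data generator, the numerical
choices, and the known limitations of `masegc`.

## Pipeline and leakage policy

The pipeline order is fixed: zero filter → KNN imputation → min–max scaling
→ moderated differential screen → SMOTE–Tomek balancing → per-modality
autoencoders → weighted latent fusion → stacking ensemble. In the default
(leakage-safe) mode every one of these stages is *fit on the outer training
fold only*: imputation donors, scaling statistics, screen selections,
synthetic minority samples, autoencoder weights and all classifiers are
derived from L_f and then applied frozen to the held-out fold. `paper_mode`
instead preprocesses and balances the whole dataset before splitting —
the order some published protocols use — which leaks synthetic copies of
test-adjacent samples into training; it exists for comparison, is recorded
in every manifest, and is off by default.

Validation metrics pool the inner out-of-fold predictions on the balanced
training set (the meta-classifier is applied to the out-of-fold base
probabilities, so base-level leakage is excluded; the meta level sees its
own training rows, which makes validation numbers slightly optimistic —
they are reported as a training-side diagnostic, not as the headline). Test
metrics pool the untouched outer folds; each sample is scored exactly once
per run.

## Preprocessing

- **Zero filter.** A feature is removed when its zero fraction strictly
  exceeds 0.6 ("more than 60%"); exactly 0.6 is retained. Applied to the
  expression modalities only by default — methylation betas are almost
  never exactly zero — and configurable.
- **KNN imputation** (k = 5). Sample-to-sample distance is Euclidean over
  co-observed features rescaled by the co-observation count; each missing
  entry takes the mean over the k nearest samples with that feature
  observed (scikit-learn's `KNNImputer` provides the distance and donor
  logic). Inside folds, held-out samples draw donors from the training
  fold only. Observed entries are never modified.
- **Min–max scaling.** Per-feature affine map to [0, 1] fit on training
  samples; held-out values outside the training range clip to the
  boundary. Constant features map to 0 — they carry no information and 0
  is the stable choice.
- **Differential screen.** A moderated two-group t-statistic: the pooled
  per-feature variance s²_g (df = n − 2) is shrunk toward a common prior,
  s̃² = (d₀s₀² + df·s²_g)/(d₀ + df), and the statistic uses df + d₀ degrees
  of freedom. The prior (d₀, s₀²) is estimated by method of moments on the
  log sample variances: the spread of log s² in excess of the chi-square
  sampling noise trigamma(df/2) is inverted through the trigamma function
  to give d₀ (infinite d₀, i.e. full shrinkage to a common variance, when
  there is no excess spread). This is a self-contained replacement for an
  external linear-model screen; it does not model a mean–variance trend
  and applies no precision weights. Selection: Benjamini–Hochberg adjusted
  p < 0.001 (step-up: q₍ᵢ₎ = p₍ᵢ₎·m/i, cumulative minimum from the largest
  rank, capped at 1). If a fold selects fewer than `min_screen_features`
  (default 8) features for a modality, the smallest adjusted p-values top
  the set up so the autoencoder always has an input; the fold log records
  the true selection count.

## Balancing

SMOTE interpolates minority samples, s = x + u·(x_nn − x) with u ~ U(0,1)
and x_nn one of the k = 5 nearest minority neighbours, until the classes
reach `target_ratio` (default 1.0). Tomek links — mutual nearest-neighbour
pairs of opposite class — are then removed (both members by default;
`majority_only` removes just the majority member), iterating until no link
remains, so a re-check of the output always returns zero links. Distance
ties resolve to the lowest sample index, so duplicated points never raise.
Balancing operates on the concatenated preprocessed feature blocks, before
encoding, and inside training folds only (see above).

A caution that matters for null-hypothesis behaviour: SMOTE-interpolated
points are geometrically distinguishable from originals (interpolation
shrinks variance toward the minority cloud's interior). When the labels
carry no signal, an ensemble trained on a SMOTE-balanced fold can learn
synthetic-vs-original structure instead, which biases raw test accuracy
toward the majority-class rate (~0.72 at 5:1 imbalance) even though
*balanced* accuracy stays at chance (~0.5). Balanced accuracy, not raw
accuracy, is the meaningful chance reference under class imbalance with
SMOTE in the loop.

## Autoencoders and fusion

One autoencoder per modality: input → 4·latent_dim (ReLU) → latent_dim
(linear), mirrored decoder with sigmoid output so reconstructions live on
the [0, 1] scale of the min–max-scaled inputs. Decoder weights are untied
by default; a `tied` flag shares transposed encoder weights (the symmetric
reading of a reused weight symbol). Latent dimension is shared across
modalities — the fusion sum requires it — with default 8 at the package's
desk scale (64 is a reasonable choice at cohort scale; no published value
exists). Fusion weights λ default to uniform 1/M; the constraint Σλ = 1 is
validated to 1e-9, and the same λ weight both the joint loss and the fused
representation.

Training is plain numpy: manual backpropagation, Adam (lr 1e-3, β 0.9/
0.999), minibatches of 32, 100 epochs at pipeline scale, everything driven
by one seeded generator. The loss trace (full-data loss before training and
after each epoch) is stored on the model; a non-finite loss raises a
training error carrying the trace. The reconstruction loss divides by the
sample count only (per-sample squared residual norm); a `per_feature`
variant divides by the feature count as well for scale-free comparisons
across modalities.

## Base learners and stacking

- SVM (RBF kernel), random forest, decision tree and AdaBoost come from
  scikit-learn; pinned no-search defaults are C = 1/γ = "scale",
  200 trees, library-default tree, 100 boosting rounds.
- Grid search (off by default at desk scale) searches the printed grids —
  SVM C ∈ {0.001, 0.01, 0.1} × γ ∈ {1, 10, 100}, RF n_estimators ∈
  {200, 500}, AdaBoost ∈ {100, 200, 300} — by stratified CV with F1
  selection and first-in-grid tie-breaking. The printed SVM grid (tiny C
  with large γ) is kept exactly as printed and is overridable.
- The 1-D CNN treats the fused latent vector as a single-channel sequence:
  two convolution blocks (kernel 3, same padding, 16 then 32 filters,
  ReLU, max-pool 2), dropout 0.3, dense softmax head; numpy with manual
  backprop, Adam, seeded; 50 epochs at pipeline scale.
- Meta-features are the five positive-class probabilities (probabilities,
  not labels — the ensemble concatenates prediction probabilities), built
  out-of-fold: learners trained on each inner-fold training part emit
  probabilities for its validation part, so no sample's meta-row comes
  from a model that saw it. The meta-classifier is XGBoost with 50 rounds,
  depth 3, learning rate 0.1, single-threaded for determinism. After
  meta-training the base learners are refit on the full outer-training set
  for deployment. Ablations drop one learner (meta width shrinks by one)
  or replace the whole stack by a single 50-round XGBoost on the fused
  latents ("no-meta").
- Decision threshold 0.5 on the meta probability; an exact 0.5 maps to the
  positive (tumor) class.

## Synthetic data generator

The generator emulates the structure the pipeline assumes, not any real
cohort's marginals. Per sample, shared latent factors are drawn N(0, 1);
on the informative factors (fraction 0.4 of 10 by default) tumor means are
shifted by `class_effect_size` (default 3.0). Each modality observes
`loadings @ factors` (sparse N(0, 0.7²) loadings, ~30% density) plus one
modality-private factor and N(0, noise_sd²) noise, through a link matched
to the layer: softplus for expression (non-negative, right-skewed) with
Bernoulli zeroing at `zero_inflation_rate` (0.3), logistic squashing into
(0, 1) for methylation with Bernoulli masking at `missing_rate` (0.1).
Defaults mirror a desk-scale tumor-heavy cohort: 200 tumor / 40 normal
samples and feature dims 300/200/60/150 (exon/mRNA/miRNA/methylation),
preserving the real layers' ordering of dimensionalities at ~1/1000 scale.

Ground-truth "informative features" are those whose induced class-mean
separation is at least one noise SD; features whose loadings on the
informative factors cancel have no mean shift and are undetectable by any
mean-difference test, so counting them would measure the generator, not
the screen. Because the class signal lives in *shared* factors, fusing
modalities genuinely helps, and the private factors ensure no single layer
suffices — the premise the fusion architecture is built on.

What passing tests on this generator do **not** show: robustness to real
RPKM dynamic range, 450K beta bimodality, batch structure, or biological
correlation patterns; the generator makes no attempt at those.

## Problem sizes and determinism

The package's reference experiment (tests and `scripts/acceptance.py`)
uses the generator defaults above with 10 outer folds, 5 inner folds,
latent dimension 8, 100 autoencoder epochs and 50 CNN epochs — sizes
chosen so the full double-loop runs in minutes on one CPU while leaving
the recovery signal unambiguous. The inner loop uses 5 folds rather than
the protocol's 10 as part of the same desk-scale choice. One master seed
fans out to per-stage seeds via CRC32 of the stage name, so stages are
independently reproducible and whole runs are bit-identical (the
determinism is asserted in the test suite on the serialized metrics JSON).

## Known limitations

- The moderated-t screen is not a voom-style weighted linear model; on raw
  counts with strong mean–variance trends its p-values would be
  miscalibrated (inputs here are min–max-scaled, which mutes the issue).
- SVC probabilities come from Platt scaling inside scikit-learn and are
  seed-dependent; determinism holds for fixed seeds and library versions.
- The validation split's meta-level optimism (above) means validation ≥
  test is expected; compare test columns across settings.
- Fusion weights are uniform by default for want of published values; the
  optional validation-fold grid over λ is exhaustive and slow.
- Binary tumor/normal only; no multiclass, no survival endpoints, no
  batch correction.
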