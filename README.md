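# masegc

Multi-omics latent fusion and stacking-ensemble classification of tumor vs
normal tissue.

Bulk tumor profiling produces several complementary molecular layers per
subject — exon-level expression, mRNA expression, mature-miRNA expression
(non-negative, zero-inflated RPKM-like values) and DNA methylation (beta
values in [0, 1] with missing entries). Each layer is high-dimensional,
noisy, and individually incomplete, and tumor cohorts are heavily
imbalanced toward tumor samples. `masegc` is a tool for researchers who
want to classify such samples by *fusing* the layers rather than picking
one: it compresses each modality with its own autoencoder, combines the
latent codes by a convex weighted sum, and classifies the fused
representation with a stacked ensemble.

## Model

For modality $i$ with (preprocessed) feature matrix $X_i$, a feedforward
encoder/decoder pair

$$Z_i^{l} = \sigma\!\big((W_i^{l})^{\top} Z_i^{l-1} + b_i^{l}\big), \qquad
\tilde{X}_i = f_d(Z_i^{L})$$

is trained to minimize the per-sample reconstruction error
$L_{\mathrm{MSE}}(X_i,\tilde X_i) = \tfrac1n \sum_s \lVert x_{is}-\tilde
x_{is}\rVert^2$. The modality losses combine as $L = \sum_i \lambda_i
L_{\mathrm{MSE}}^{(i)}$ with $\lambda_i \ge 0,\ \sum_i \lambda_i = 1$, and
the same weights fuse the latent codes into one representation per sample:

$$Z = \sum_{i=1}^{M} \lambda_i Z_i^{L}.$$

$Z$ feeds a stacking ensemble: five base learners (RBF-kernel SVM, random
forest, decision tree, AdaBoost, and a 1-D CNN over the latent vector)
produce out-of-fold positive-class probabilities for every training sample;
an XGBoost meta-classifier (50 boosting rounds) is trained on those
probability vectors, and the refit base learners plus meta-model classify
new samples. Tumor is the positive class, so specificity measures
normal-tissue recognition.

Around the model sits a leakage-aware pipeline, refit inside every
cross-validation training fold:

1. **zero filter** — expression features with zeros in more than 60% of
   samples are dropped;
2. **KNN imputation** — missing methylation betas imputed from the k = 5
   nearest samples (missing-aware Euclidean distance);
3. **min–max scaling** to [0, 1], training-fold statistics applied to
   held-out samples with clipping;
4. **differential screen** — an empirical-Bayes moderated two-group
   t-statistic per feature, Benjamini–Hochberg adjusted, selected at
   adjusted p < 0.001;
5. **SMOTE–Tomek balancing** — minority-class interpolation to parity
   followed by removal of Tomek links (mutual opposite-class nearest
   neighbours).

A `paper_mode` switch reproduces the global (pre-split) scaling and
balancing order that some published protocols use instead.

## Worked example

The bundled config simulates a four-modality cohort of 80 subjects (60
tumor / 20 normal, class effect 3 SD on the shared latent factors) and
cross-validates the full pipeline over 5 outer folds:

```bash
masegc run --config examples/quickstart.yaml --out results/quickstart
cat results/quickstart/summary.tsv
```

```
split       accuracy  precision  recall  f1      specificity
validation  1.0       1.0        1.0     1.0     1.0
test        0.975     1.0        0.9667  0.9831  1.0
```

The validation row pools the inner out-of-fold predictions on the
(balanced) training folds; the test row pools the untouched outer test
folds, each sample scored exactly once. Here 2 of 60 tumor samples are
missed on held-out data (recall 0.9667) and no normal sample is
misclassified (specificity 1.0). Per-fold confusion matrices land in
`results/quickstart/confusion/`, full-precision metrics with provenance in
`metrics.json`.

Every stage is also a subcommand (`simulate`, `preprocess`, `balance`,
`encode`, `train`, `predict`, `evaluate`, `ablate`) operating on Xena-style
TSV matrices (rows = features, columns = samples; labels as a two-column
`sample_id<TAB>tumor|normal` table).

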