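# Desk-scale end-to-end run: simulate a four-modality cohort with a clear
# tumor/normal signal, then cross-validate the full pipeline.
simulate:
  n_samples_per_class: [60, 20]   # tumor, normal (3:1 imbalance)
  feature_dims: {exon: 120, mrna: 80, mirna: 30, methylation: 60}
  class_effect_size: 3.0
  seed: 7
pipeline:
  outer_folds: 5
  inner_folds: 3
  latent_dim: 8
  ae_epochs: 60
  cnn_epochs: 30
  seed: 7
out_dir: results/quickstart
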