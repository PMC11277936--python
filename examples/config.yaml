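# Desk-scale run configuration: one file drives every pipeline stage.
seed: 1
outdir: runs

cohort:
  n: 2000            # development-scale: 6445
  prevalence: 0.3963 # ~2554/6445 positive
  small_share: 0.3027 # ~773/2554 of positives are small lesions
  size_threshold_px: 12   # pixel analog of the ACCP 3 cm rule

curriculum:
  increment: 0.05    # small-lesion share of positive slots added per stage
  auc_min: 0.95      # strict transition gates
  sens_min: 0.80
  spec_min: 0.80
  patience_epochs: 1

training:
  epochs_max: 30     # development-scale: 400
  batch_size: 32
  lr0: 0.001
  lr_patience: 10
  dropout: 0.5
  rotation_max_deg: 30
  flip_prob: 0.5

ablation:
  seeds: [0, 1, 2, 3, 4]
  epochs_max: 30
  val_fraction: 0.3
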