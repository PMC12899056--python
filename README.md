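# neoseiz

Cross-subject neonatal EEG seizure detection toolkit: multi-annotator
consensus labeling, STFT spectrogram preprocessing, and a domain-adversarial
spatio-temporal detector (channel-independent CNN → spatial Bi-LSTM →
attention pooling → gradient-reversed domain head), with subject-level
cross-validation, data-scaling and ablation experiments. A bundled synthetic
cohort generator makes the whole pipeline testable without any clinical data.

The neural network runs on a small NumPy reverse-mode autodiff engine
(`neoseiz.nn`) — no deep-learning framework is required.

## Pipeline overview

| module | role |
| --- | --- |
| `neoseiz.synth` | synthetic multi-subject cohorts: 1/f^β backgrounds with per-subject amplitude gain (domain shift), focal rhythmic bursts, three noisy annotators |
| `neoseiz.consensus` | per-second majority vote, annotation disagreement rate (ADR), ADR-ranked subject selection |
| `neoseiz.preprocess` | 18-channel bipolar montage, 256→128 Hz downsampling, 2-s windows (50 % train overlap, centre-second labels), Hann/64-point/hop-16 log-STFT → 18×33×17 tensors, train-set global z-score |
| `neoseiz.model` | channel folding, truncated-residual CI-CNN (1536-dim per-channel features), 18-step spatial Bi-LSTM (512-dim), attention or mean pooling, label + gradient-reversed domain heads, weighted cross-entropy (w_pos = 2.5) |
| `neoseiz.training` | AdamW (lr 1e-4, wd 1e-5, batch 32), adversarial λ schedule, early stopping on validation AUC, leakage guards |
| `neoseiz.evaluation` | accuracy/sensitivity/specificity/F1/AUC, stratified subject-level 5-fold CV, source-data γ-scaling experiment, 4-variant ablation (baseline/att/da/full), attention-map export |

## CLI

```bash
neoseiz simulate --config cohort.yaml --out cohort/        # EDF + annotations.csv + truth.csv
neoseiz select --annotations cohort/annotations.csv \
    --groups groups.csv --k-per-group 15 --out selection.csv
neoseiz preprocess --edf-dir cohort/ --annotations cohort/annotations.csv \
    --role train --out windows_train/
neoseiz train --train-windows windows_train/ --val-windows windows_val/ \
    --config train.yaml --out run/
neoseiz evaluate --checkpoint run/checkpoint --windows windows_val/ \
    --out metrics.json --attention-out attention.csv
neoseiz cv --cohort-config cohort.yaml --config train.yaml --out cv_out/
neoseiz scale-experiment --cohort-config cohort.yaml --out scaling.csv
neoseiz ablate --cohort-config cohort.yaml --variants baseline,att,da,full \
    --out ablation.csv
```

YAML configs carry `CohortConfig` fields (simulate/cv/ablate) or
`ModelConfig` + `TrainConfig` fields (train); all fields are optional and
default to the reference values.

## Notes

- Real-data mode reads 19-electrode 10–20 EDF recordings plus a
  per-second, 3-expert `annotations.csv`; synthetic and real data flow
  through the same code paths.
- Checkpoints are a `weights.npz` blob plus a JSON sidecar (model config,
  normalization statistics, montage order, domain index map).
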