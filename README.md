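# emrfuse

Multimodal EMR diagnosis toolkit. `emrfuse` fuses structured clinical fields
(categorical + continuous labs) with free-text report units through a gated
cross-attention transformer, aligned across modalities with a symmetric
InfoNCE contrastive objective, and ships a seeded synthetic cohort generator
so the entire pipeline — preprocessing, training, ablations — runs end to end
without any patient data.

## What's inside

| Module | Purpose |
| --- | --- |
| `emrfuse.schema` | Cohort data model: feature schema (11 structured fields + 2 text units by default), record validation, winsorization, clinically-aware imputation (afebrile CRP baseline of 3.5 mg/L, training-split means/modes), z-score standardization, one-hot encoding for baselines |
| `emrfuse.synthetic` | Seeded synthetic cohort generator with a plantable cross-modal label signal (closed-form Bayes-optimal accuracy available as a test oracle) |
| `emrfuse.encoders` | Offset categorical embedding (shared table, collision-free per-field offsets, reserved unknown slots), per-field affine numeric embedding, hash tokenizer + tiny seeded transformer text backbone + projection layer |
| `emrfuse.fusion` | Bidirectional gated cross-attention, residual fusion blocks with learnable fusion coefficients, full classifier forward pass |
| `emrfuse.objectives` | Shared projection head, symmetric InfoNCE with learnable clamped temperature, class-weighted cross-entropy, joint weighted objective |
| `emrfuse.crossval` | Stratified k-fold plans, leakage-free per-fold preprocessing, training loop with early stopping, ablation variants and tabular/text baselines |
| `emrfuse.nn` | Minimal NumPy reverse-mode autodiff engine (tensors, layers, Adam) that the model runs on — no deep-learning framework required |

## CLI

```bash
emrfuse simulate   --seed 7 --out out/sim            # cohort CSV + summary + config echo
emrfuse preprocess --seed 7 --out out/prep           # imputed cohort + imputation log
emrfuse train      --seed 7 --out out/train          # 5-fold CV training, metrics + curves
emrfuse evaluate   --seed 7 --out out/eval           # single-modality baselines
emrfuse ablate     --seed 7 --out out/abl            # component-removal study
emrfuse report     --metrics-json out/train/metrics.json --out out/report
```

All commands accept `--config <yaml>` with `cohort:`, `model:` and `train:`
sections mirroring `emrfuse.config`; every source of randomness flows from
the seed, and identical config + seed reproduces byte-identical cohorts and
metrics.

Averaged cross-validation metrics are reported under two labeled
conventions — `mean_of_folds` and `pooled_confusion` — because the harmonic
F1 identity does not survive averaging.

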