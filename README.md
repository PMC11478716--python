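# sleepbelt

Analysis pipeline for wearable-belt sleep-apnea monitoring: quality-filtered
heart-rate-variability (HRV) and breathing-rate-variability (BRV) feature
extraction from whole-night ECG and thoracic-excursion recordings, with
device-agreement, severity-classification and repeatability analyses. A
synthetic cohort generator produces paired belt/PSG recordings with
AHI-driven variability structure, so the full pipeline can be exercised and
validated end to end without clinical data.

## What it does

- **`sleepbelt.synthetic`** — whole-night paired belt/PSG ECG (sum-of-Gaussians
  PQRST morphology) and excursion waveforms; apnea events scheduled from a
  per-subject AHI drive cyclic bradycardia/tachycardia and breathing pauses;
  contiguous-block artifact injection; per-subject random effects for
  multi-night intra-class correlation; fast feature-level simulators.
- **`sleepbelt.ecg`** — R-peak detection (derivative-energy, 200 ms
  refractory) and 15-s segment template-correlation quality grading: each
  beat's QRS / PQRST complex is correlated against the segment's median
  reference; acceptance needs r > 0.98 (strict) on either complex, with a
  fallback RR-plausibility rule (333–2000 ms, ≤ 33 % deviation from the
  segment median).
- **`sleepbelt.breath`** — breathing-cycle detection and 32-s template
  matching with phase-wise (inhale/exhale) time normalization; acceptance
  at r ≥ 0.75 (inclusive); breath-to-breath intervals outside
  5–50 breaths/min are excluded.
- **`sleepbelt.variability`** — SDNN, pNN50, rMSSD, IRRR, MADRR, triangular
  index; ULF/VLF/LF/HF band powers from short-time Fourier transforms of the
  cubic-interpolated interval signal in 300-s windows, plus the LF/HF ratio.
- **`sleepbelt.agreement`** — Bland-Altman bias and 95 % limits of agreement
  for whole-night mean instantaneous heart and breathing rates (belt − PSG).
- **`sleepbelt.classify`** — two-class RBF SVM on HRV, BRV or combined
  feature sets with AHI-quantile labels, Mann-Whitney AUC with DeLong CIs,
  Youden operating point, and leave-one-out cross-validation.
- **`sleepbelt.repeatability`** — random-intercept REML variance components;
  repeatability R = between-subject / total variance with parametric
  bootstrap CIs, summarized as median + IQR across features per channel.
- **`sleepbelt.pipeline` / CLI** — one-config orchestration with
  deterministic seeded outputs and a manifest.

## CLI

```bash
# full demo run (simulate -> filter -> features -> analyses)
sleepbelt run --out results/demo --seed 1

# individual stages
sleepbelt simulate --n-subjects 8 --seed 1 --duration 1800 --out results/sim
sleepbelt ecg --in results/sim/S001_n1_ecg_belt.csv --out results/ecg
sleepbelt breath --in results/sim/S001_n1_excursion_belt.csv --out results/breath
sleepbelt classify --features results/demo/features_belt.csv --out results/clf
sleepbelt repeat --features results/demo/features_belt.csv --out results/rpt
```

All thresholds (segment lengths, correlation thresholds, RR/BB bands,
spectral window and band edges) live in `RunConfig` and the corresponding
CLI flags; defaults equal the published analysis constants.

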