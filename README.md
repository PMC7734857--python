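# hrvoutcome

Heart-rate-variability (HRV) feature engineering and genetic-algorithm
feature selection for predicting ICU discharge outcome from continuous
ECG-derived RR-interval series — the setting is severe traumatic brain
injury, where illness-severity scores (APACHE II/III, SAPS) are the
usual baseline predictors and beat-to-beat variability is a candidate
"electronic biomarker" of autonomic failure.

The package is aimed at biosignal/biostatistics researchers who want a
tested, fully reproducible implementation of this analysis style, plus a
synthetic cohort generator so every stage can be exercised and calibrated
without access to patient data.

## The pipeline

1. **Per-epoch HRV parameters** (`hrv_features`). An RR series is cut
   into consecutive 30-minute epochs; each complete epoch yields 20
   parameters: time domain (HR, mean RR, SDNN, RMSSD, CVRR), frequency
   domain via Welch PSD of the 4 Hz cubic-spline-resampled tachogram
   (peak frequency, absolute power, relative power for VLF/LF/HF, LF/HF
   ratio, normalized units, total power) and the Poincaré dispersions
   SD1/SD2.
2. **Sliding-window distance features** (`distance_features`). For each
   parameter F and time point t, the Euclidean norm over the following
   n = 8 epochs,

   DistF(t) = √(F_t² + F_{t+1}² + … + F_{t+7}²),

   summarises the parameter's recent magnitude; a 48-epoch record gives
   41 distance rows.
3. **Outcome models and GA selection** (`model_selection`). Rows are
   (patient, time point) vectors; the classifier is ridge-stabilised
   logistic regression. A binary-chromosome genetic algorithm searches
   feature subsets with the cross-validated Youden index
   (J = sensitivity + specificity − 1 at the 0.5 probability cutoff) as
   fitness, repeated runs voting on the final set.
4. **Evaluation** (`evaluation`). Five repeats of five patient-grouped
   folds; each test fold holds one non-survivor and 20% of survivors
   with five sampled time points each (25 test rows); train/test AUC,
   sensitivity and specificity with normal-approximation 95% CIs,
   identical folds shared by all compared models.
5. **Synthetic cohorts** (`synthetic`). RR generators with LF/HF/VLF
   oscillations, broadband noise, circadian drift and outcome-dependent
   effect sizes (variability depression and hourly decay in
   non-survivors, truncated records, score surrogates).

## Worked example

```python
from hrvoutcome import (CohortConfig, CVScheme, gen_cohort, make_folds,
                        compare_models)
from hrvoutcome.evaluation import format_report_markdown

dataset, truth = gen_cohort(CohortConfig(record_hours=12.0, rng_seed=7))
folds = make_folds(dataset, CVScheme(rng_seed=7))
report, _ = compare_models(
    {"APACHE II": ["APACHE_II"],
     "HRV distance": ["DistSDNN", "DistTotal_ms_sq"]},
    dataset, folds=folds)
print(format_report_markdown(report))
```

prints

```
| Set | Features | Train AUC | Train Sens | Train Spec | Test AUC | Test Sens | Test Spec |
|---|---|---|---|---|---|---|---|
| APACHE II | APACHE_II | 0.68 [0.65, 0.70] | 0.00 [0.00, 0.00] | 1.00 [0.99, 1.00] | 0.65 [0.51, 0.79] | 0.00 [0.00, 0.00] | 0.96 [0.91, 1.01] |
| HRV distance | DistSDNN DistTotal_ms_sq | 1.00 [1.00, 1.00] | 1.00 [1.00, 1.00] | 1.00 [1.00, 1.00] | 1.00 [1.00, 1.00] | 0.94 [0.88, 0.99] | 1.00 [1.00, 1.00] |
```

On this cohort the non-survivors were generated with halved oscillation
amplitudes and a 3%/hour variability decay, so the variability distance
features separate the groups almost perfectly (test AUC 1.00, test
sensitivity 0.94 at the 0.5 cutoff), while the severity-score surrogate
— built to discriminate only moderately — reaches test AUC 0.65 and,
like several score-based models in this literature, predicts no
non-survivors at the default cutoff (sensitivity 0.00).

The same pipeline is scriptable from the shell:

```bash
hrvoutcome simulate --config cohort.yaml --out-dir data/
hrvoutcome features --rr data/S01.txt --epoch-min 30 --out feats.csv
hrvoutcome distf    --features data/features.csv --window 8 --out dist.csv
hrvoutcome select   --features data/features.csv --distf dist.csv \
                    --labels data/labels.csv --config ga.yaml --out sel.json
hrvoutcome evaluate --features data/features.csv --distf dist.csv \
                    --labels data/labels.csv --sets sets.json --out-dir report/
```

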