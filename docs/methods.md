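# Methods

This note documents the models, conventions and design choices behind
`hrvoutcome`, and what the synthetic experiments do and do not show.

## HRV parameters per epoch

RR intervals are assigned to consecutive half-open 30-minute epochs
`[k·30 min, (k+1)·30 min)` by beat-onset time; a trailing partial epoch
is dropped, and rows are numbered from time point 1. Epochs that fail a
sub-analysis precondition keep their row with missing values in the
affected columns, so time-point indices stay aligned across patients.

Time domain: mean RR (ms); HR as the mean of per-beat instantaneous
rates `60000/RR_k` (the convention of common HRV software; `60000 /
mean(RR)` is available via `hr_method="mean_rr"` — with real epoch-level
variability the two differ by well under 0.5 beats/min); SDNN as the
sample standard deviation (n−1), matching the Task-Force/Kubios
convention; RMSSD as the root mean squared successive difference;
CVRR = SDNN/RR.

Frequency domain: the tachogram RR(t) is cubic-spline interpolated at
4 Hz over the epoch's beat-time range (requires ≥ 4 beats spanning
≥ 60 s), linearly detrended, and its PSD estimated by Welch's method
with 256-s Hann windows at 50% overlap. Band limits are VLF [0, 0.04),
LF [0.04, 0.15), HF [0.15, 0.4] Hz; ULF is not computed. Absolute band
power is the PSD integral over the band (ms²); `Total_ms_sq` is the
full-spectrum integral, so relative band powers may sum to less than
100%. Normalized units follow the Task-Force definition in which the
"total power" entering the denominator extends only to the HF upper
limit: LF_nu = LF/(LF+HF)·100, hence LF_nu + HF_nu ≡ 100 whenever
defined. LF/HF is reported missing when HF power is zero. Linear
detrending is a deliberate, simpler substitute for smoothness-priors
detrending; it is configurable (`SpectralConfig.detrend`) and documented
here because exact numerical agreement with any specific HRV software's
defaults is not claimed.

Poincaré: SD1 = √(SDSD²/2) and SD2 = √(2·SDNN² − SDSD²/2) with SDSD the
sample standard deviation of successive differences and the SD2 radicand
clamped at zero (alternating series genuinely reach the clamp). These
satisfy SD1² + SD2² = 2·SDNN² exactly and agree with the rotated-axes
(ellipse) definition of SD1.

An optional artifact pre-filter (drop intervals outside [300, 2000] ms
or jumping > 20% from the previous accepted beat) exists but is off by
default; removal compacts the time axis, so it is meant for lightly
contaminated records.

## Distance features

DistF at time point t is the Euclidean norm of the n = 8 consecutive
values F_t…F_{t+7} — the distance of the window vector from an all-zero
baseline. Raw, unstandardised values enter the norm (the published
worked values match raw HR/RR magnitudes), which makes DistF
scale-dependent across features; an optional per-patient z-scoring
switch exists and is off by default. Windows containing missing values
produce a missing distance with the row retained. A T-epoch record
yields T − 7 rows; the window for row t is always [t, t+7], verified
against a brute-force reimplementation in the tests.

## Outcome models

Rows of the design matrix are (patient, time point) pairs: plain HRV
parameters at the time point, distance features at the same time-point
index, severity scores constant within a patient, outcome label
replicated per row. The positive class is non-survival throughout.

The classifier is logistic regression fitted by Newton/IRLS with a
ridge penalty of 1e-4 on the coefficients (intercept unpenalised) and a
backtracking line search. The penalty exists because 25-row test folds
and near-separable synthetic cohorts make unpenalised MLE diverge; it is
small enough that well-conditioned fits match scikit-learn's equivalent
(`C = 1e4`) to three decimals, as the tests verify against both
scikit-learn and a brute-force grid minimisation of the penalised
likelihood. Predictions are clipped to [1e-12, 1 − 1e-12]. Classification
uses probability strictly greater than 0.5; a probability exactly at the
cutoff is negative. Feature standardisation before fitting is available
(training-fold statistics only) and off by default.

## Cross-validation protocol

Five repeats of five patient-grouped folds. Per repeat, non-survivors
are permuted and dealt one per fold (rotation when counts differ);
survivors are permuted and each fold takes `floor(0.2 · n_survivors)` of
them — 4 of 21, matching the protocol's stated fold size; one survivor
per repeat is therefore never tested. Each test patient contributes five
time points drawn uniformly without replacement from time points with a
valid 8-epoch window (all available ones, with a warning, if fewer than
five exist). Training uses every valid row of every patient *not* in the
test fold; the alternative reading that keeps test patients' unselected
rows in training is available as `paper_literal=True` but leaks
within-patient information and is not the default. Folds are built once
per scheme seed and shared by every compared model.

Metrics per (repeat, fold) cell: train/test Mann–Whitney AUC,
sensitivity, specificity at the 0.5 cutoff. Aggregates are the mean over
cells with a normal-approximation 95% CI (mean ± 1.96·SE over the 25
cells); a bootstrap alternative was considered and rejected as default
because the printed-CI convention this mirrors is symmetric. **Known
limitation:** the fold-level SE treats cells as independent, but all
cells share the same handful of non-survivors, so the interval is
anti-conservative at the 26-patient study scale — on null cohorts it
covers 0.5 in only about half of the seeds (the package's own null
experiment measures this), because per-cohort chance alignment of five
non-survivors moves the AUC by ±0.17 while the internal CI half-width is
about 0.1. No internal resampling at this cohort size can absorb
cohort-level sampling variation; conclusions from such small grouped
protocols should rest on external replication, not the internal CI.

## Genetic algorithm

Binary chromosomes over the candidate features (default: the 20 HRV
parameters plus their 20 distance features). Tournament selection (size
3), uniform crossover at rate 0.8, per-bit mutation at 1/length,
two-member elitism, population 50, 100 generations, 100 repeated runs —
all configurable; these values are standard small-GA defaults, since the
method's original description leaves them open. Fitness is the mean
per-fold Youden index of a cross-validated logistic fit on the selected
columns (an empty chromosome scores −1); fold design matrices are
precomputed once, fitness values are cached per chromosome, and the
Newton iteration count is bounded — on separable folds the decision
boundary stabilises long before the coefficients.

Chromosomes tie-break by subset size: among equal-fitness chromosomes
the smaller wins, in selection, elitism and best-tracking
(`GAConfig.parsimony_ties`, on by default). Without this, fitness
plateaus let uninformative bits drift through selection into the
reported sets. A consequence worth knowing: with a *constant* fitness
landscape the GA collapses to minimal chromosomes; with the tie-break
disabled, selection frequencies sit near 0.5 per feature, and the tests
assert both behaviours. Repeated runs vote: the final set contains
features selected in more than half the runs' best chromosomes (the
threshold is configurable; if nothing clears it, the single most
frequent feature wins, ties resolved by the higher mean fitness of runs
containing the feature).

Best-so-far fitness is non-decreasing within a run (elitism), identical
seeds reproduce the full `SelectionResult` bit-for-bit, and all
randomness flows from `numpy.random.default_rng` seeded per run as
`[rng_seed, run_index]`.

## Synthetic cohorts

`gen_rr_series` integrates an instantaneous RR model — mean level, an LF
sinusoid near 0.1 Hz, an HF sinusoid near 0.25 Hz, a VLF oscillation
near 0.015 Hz, a circadian-period drift and per-beat Gaussian broadband
noise — emitting beats at cumulative RR times (a nominal beat grid with
one fixed-point refinement; accurate to well under a beat). An hourly
multiplicative decay can shrink the LF/HF amplitudes and broadband noise
over the record. This is a controlled spectral stand-in, not a
physiological ECG simulator: it gives the frequency-domain features real
structure at known ground truth, but contains no ectopy, no arrhythmia,
no respiration coupling and no nonstationarity beyond the decay and
drift. Passing tests therefore demonstrate correctness of the pipeline's
computations and the qualitative behaviour of the protocol, not clinical
performance on real ICU recordings.

The default cohort reproduces the study-like structure: 21 survivors and
5 non-survivors with 24-hour records in 30-minute epochs, two
non-survivors truncated to 6–12 h (the lower bound keeps at least five
valid distance windows so every test fold has its full 25 rows).
Non-survivors draw the same base parameters as survivors, then have
LF/HF amplitudes and broadband noise multiplied by 0.5 and a 0.97/hour
variability decay applied — the depressed-variability signature
repeatedly reported after severe brain injury. Severity-score surrogates
are Gaussian with group-shifted means (e.g. APACHE II 15 ± 6 vs
19.5 ± 6), with overlap set so a score-only classifier reaches an AUC
near 0.7, the neighbourhood of published score baselines. No
distributional summaries of the original cohort are available, so the
base parameter distributions (mean RR 900 ± 70 ms, LF amplitude 30 ± 6
ms, HF 20 ± 4 ms, VLF 15 ± 4 ms, broadband 25 ± 5 ms, drift 12 ± 3 ms)
are plausibility choices for sedated adult ICU patients, fixed once; the
drift amplitude is kept small enough that the mean RR of any ≥ 2-hour
record stays within 2% of nominal. Setting every group multiplier to 1
and the decay to 1 (`CohortConfig.null()`) makes the groups
exchangeable.

### The planted-recovery experiment

`gen_planted_cohort` exists for one purpose: a ground-truthed test of
the GA wrapper. Designing it is a small identifiability problem, and the
naive designs fail for instructive reasons: deficits applied to all
variability components make every variance aggregate (SDNN, total and
relative powers) a proxy for the planted features; two-pathway deficits
(some patients lose LF, others HF) form an OR-condition a linear
logistic model cannot express; and ratio features reconstruct one band
power from the other. The final design plants a **sympathovagal balance
shift**: each patient's LF and HF amplitudes are A·cos θ and A·sin θ
with the combined oscillatory power A²/2 identically distributed in both
groups and only the balance angle θ differing (survivors 36–55°,
non-survivors 15–34°, i.e. LF-dominant — the sympathetic-predominance
signature described for critically ill patients). Every variance
aggregate is then distribution-identical between groups by construction;
the outcome signal lives in exactly two candidate distance features,
DistLF_ms_sq (up) and DistHF_ms_sq (down); either band alone overlaps
between groups through the amplitude spread, while together they recover
the balance — a linearly separable cone. Ratio features are excluded
from the 10-feature candidate list. The experiment uses 45 survivors and
15 non-survivors with 8-hour records: larger than the study cohort,
deliberately, so that recovery measures the selection machinery rather
than small-sample chance (with only five non-survivors, noise features
chance-separate the groups with cross-validated Youden values up to
0.95, and no wrapper can be expected to beat that reliably).

## Problem sizes and determinism

The statistical experiments run at sizes chosen to give stable answers
on a single CPU: 12-hour records for the null-calibration and
signal-comparison cohorts (24 epochs, 17 distance windows), 8-hour
records for recovery cohorts, 20 seeds per experiment in the test suite
and 8 in the acceptance script, and a reduced GA budget (population 30,
40 generations, 3 voting runs) for recovery. Every stochastic component
is driven by an explicit seed; the acceptance script derives all of its
seeds from its `--seed` argument.

## Known limitations

- The spectral path does not reproduce any specific HRV software's
  smoothness-priors detrending or interpolation defaults; cross-software
  numerical agreement is not claimed.
- The fold-level CI is anti-conservative under patient clustering (see
  above) — reported, measured, and left visible rather than patched.
- Distance features on raw scales make coefficient magnitudes
  incomparable across features; use the z-scoring switches if
  comparability matters.
- The RR generator's stand-in nature means real-data artifact handling
  (ectopy, missed beats) is exercised only through the simple optional
  pre-filter.
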