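# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `cpecast`, in the package's own words.

## Problem setting

An admission is a sequence of timestamped integer NRS pain scores (0–10)
recorded to the minute. A **cancer pain exacerbation (CPE)** is any τ-length
time bin whose recorded score is ≥ 4. Given the binned scores of the
preceding *L* hours, the task is to emit, in one forward pass, the
probability of CPE for each of the 24/τ bins of the next calendar day
(non-autoregressive multi-horizon binary classification).

## Pre-processing

* **Binning.** The day is partitioned into 24/τ half-open bins
  [start, start+τ), τ ∈ {1, 2, 3, 4, 6, 8, 12}. Multiple records in a bin
  collapse to their **maximum** NRS; a bin with no record is imputed to 0
  (patient treated as pain-free). Same-minute duplicate events keep the
  maximum, consistent with the bin rule.
* **Transformation.** Zero padding extends each admission's timeline so it
  starts and ends at 0:00, turning an *n*-day record into a (24/τ) × *n*
  matrix with one column per calendar day. Flattening the matrix
  column-major recovers the padded vector exactly.
* **Samples.** One forecast sample per calendar day, anchored at midnight
  (no sub-day sliding): day *d* is a forecast day iff the *L*/24 preceding
  calendar days all exist in the matrix, so inputs contain only real
  admission time and are never padded backwards beyond admission. Windows
  therefore start at day *L*/24 + 1; an *n*-day admission yields
  max(0, *n* − *L*/24) samples. Inputs are the raw integer NRS magnitudes
  (scaled by 1/10 into [0, 1] at the model boundary, matrices stay integer);
  targets are the forecast day's binary CPE labels. The zero-imputation
  convention makes "no record" and "no pain" deliberately indistinguishable,
  which is part of the task definition, not an artifact.
* **Split.** Train/test is an 80–20 holdout at the **patient** level; all
  admissions of a patient travel together.

## Models

Six trainable architectures, each three stacked blocks of its kind followed
by one dense sigmoid head over the final summary state:

| architecture | block | notes |
|---|---|---|
| RNN | Elman tanh recurrence | |
| LSTM | fused-gate LSTM | forget bias init 1 |
| GRU | standard 2-gate GRU | |
| Bi-LSTM | forward + reversed LSTM | width halved per direction; summary joins both final states |
| CNN-LSTM | width-3 same-padded conv → 2 LSTM blocks | minimal hybrid that keeps 3 blocks |
| Transformer | post-norm encoder layer | 2 heads, sinusoidal positions, feed-forward width tied to the model width; "block" = one encoder layer |

For fairness the six parameter counts are matched by exhaustive integer
width search against an LSTM reference (width 12 by default): every count is
as close as possible to the reference and the max−min spread must stay
within 3,000 trainable parameters (at L = 24 h, τ = 1 h the spread is 272).
"Parameters" means trainable scalar weights — the only countable reading.

The **base model** is the untrained reference: its probability for output
slot *s* is the mean CPE indicator at slot *s* over the window's prior days.
Averaging binary indicators (not raw NRS) makes its output directly a
probability comparable with the sigmoid outputs under the shared 0.5
threshold; it is invariant to magnitudes above/below the threshold by
construction.

The networks run on a small reverse-mode autodiff core over numpy arrays.
The LSTM — the grid's workhorse — uses a fused step with a hand-derived
backward-through-time pass (numba-JIT kernels, with a vectorized numpy
fallback); all gradients are verified against central finite differences in
the test suite (absolute agreement ~1e-11).

## Training

* Loss: prevalence-balanced binary cross entropy, w₊ = 1/(2p), w₋ =
  1/(2(1−p)), with p computed once from the training partition at the
  experiment's τ; probabilities clamped to [1e-7, 1−1e-7] before the log.
* Optimizer: Adam at a constant 1e-4 under **stochastic weight averaging** —
  from epoch 5 on, every epoch's end-of-epoch weights enter a running mean,
  and the averaged weights are the returned model (a 300-epoch run averages
  exactly 296 checkpoints). SWA needs a base optimizer; an Adam-style
  adaptive update is the conventional choice when none is specified, and the
  averaging period is read in epochs. No validation split or early
  stopping: the schedule is fixed at 300 epochs, batch size 100.
* Determinism: model initialization, batch order and the generator all draw
  from explicit seeds; identical seed + data reproduce identical weights.

## Evaluation

Prediction is scored as independent per-bin binary classification, pooled
over all bins of all test samples (micro pooling): one confusion matrix, one
ranking. Metrics: MCC (primary, robust to the class imbalance that moves
from 6 % positives at τ = 1 h to ≈44 % at τ = 12 h), AUROC (rank /
Mann–Whitney with tie averaging) and AUPRC (precision-recall step
integration). Numerical conventions, chosen once and not tuned:

* decision threshold fixed at 0.5 for every model and cell, probability
  exactly 0.5 counts as positive;
* MCC with any zero marginal is scored 0 (standard degenerate-case
  convention);
* one-class test sets leave AUROC/AUPRC as missing (NaN), never silently
  dropped.

A per-admission view of the same machinery (`per_admission_results`)
supports case reports.

## Synthetic cohort

No public pain-log corpus with this structure exists, so the generator is a
first-class, calibrated simulator. Per patient: a frailty offset
(Normal(0, 1.0)); per day: a latent pain level = baseline 2.0 + frailty +
AR(1) deviation (persistence 0.80, stationary sd 1.9) + 2.8 during acute
episodes (daily start probability 0.07, mean length 2.5 days). Records:

* **Scheduled**: rounding passes at 8:00, 17:00 and (less attended) 21:00,
  with up to 2 h of jitter emulating the spread of a pass over the ward;
  recorded score = daily level − 1.6 + momentary noise (sd 1.15), i.e.
  routine scores capture background pain, sitting below the momentary peaks
  that trigger patient calls.
* **Unscheduled**: candidate sudden-pain moments (4.8/day, timed by a
  near-uniform day-weighted circadian profile) become records only when
  momentary pain ≥ 4 — patients call the nurse for rescue medication — with
  a 4-h refractory period afterwards while the rescue dose acts.
* Admission length: log-normal, median 15 days, truncated to [5, 60], with
  the log-length shifted by 0.35 × frailty (sicker patients stay longer).

Three of these mechanisms deserve their rationale spelled out, because the
published summary statistics cannot coexist without them:

1. **Background-vs-breakthrough offset.** If routine rounding scores sat at
   the same level as the momentary peaks, the fixed rounding windows would
   impose a strong hour-of-day mean structure on the binned series, flooring
   the pooled lag-5 correlation near 0.2; observed wards show ≈0.08.
2. **Rescue refractory period.** Without it, the per-admission median of
   CPE events/day (≈1.0) and the 1-h CPE bin fraction (≈6 %) cannot both
   hold: multi-call days inflate event counts faster than bin counts.
3. **Frailty–length coupling.** Pooled bin fractions weight long admissions
   more than per-admission medians do; coupling length to frailty raises the
   pooled CPE fractions to the observed values without moving the medians.

Defaults were calibrated **once** against seven published ward statistics
(records/day 2.74 and CPE/day 1.01 medians; CPE fractions 6.0 % at τ = 1 h
and 44.5 % at τ = 12 h, the latter an emergent clustering check, not
separately tuned; pooled day-lag correlations ≈0.20 / ≈0.08 at lags 1 / 5
for 1-h bins and ≈0.53 at lag 1 for 12-h bins) and then frozen; the
calibration is stable across seeds at 500 patients.

What the generator does **not** emulate: diagnoses and treatment covariates,
opioid pharmacokinetics, dose-escalation feedback (pain management reducing
future CPE), weekday/weekend staffing effects, and non-stationary
trajectories (e.g. post-transplant conditioning courses). Passing tests
therefore show that the pipeline recovers structure *of the kind the
generator produces* at realistic sparsity and imbalance — not that any
architecture ranking would transfer to real EMR data.

## Scaled-down experiment sizes

The test suite reproduces two published qualitative trends on desk-scale
cohorts of 200 patients, averaged over seeds {11, 13, 17, 19, 23}: the
trained LSTM beats the averaging base model on MCC at both τ = 1 h and
τ = 12 h (L = 120 h), and the LSTM's MCC is higher at τ = 12 h than at
τ = 1 h. The 12-h cells run the full 300-epoch schedule; the 1-h cells
(12× longer sequences) run 40 epochs, enough for the ordering to be stable
across seeds. The acceptance script regenerates the 500-patient calibrated
cohort and recomputes the seven cohort statistics from scratch.

## Known limitations

* The per-cell decision threshold is fixed at 0.5; threshold tuning would
  change absolute MCC but is deliberately excluded to keep the baseline
  comparison honest.
* The pooled Pearson correlations include the padded edge days (structural
  zeros), matching the transformation's convention; excluding them shifts
  the correlations by a few hundredths.
* Whether models should consume NRS magnitudes or binarized CPE indicators
  is undetermined by the task statement; this implementation feeds
  magnitudes (the transformation operates on NRS records) — the base model
  alone is indicator-based by definition.
* MCC comparisons between architectures on the synthetic cohort inherit its
  simplifications; small inter-architecture differences (≲0.02) should not
  be over-read.
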