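# cpecast

Forecasting the onset timing of **cancer pain exacerbation (CPE)** in
hospitalized patients from sparse numerical-rating-scale (NRS) pain logs.

Inpatient pain is recorded as ordinal NRS scores (0 = no pain … 10 = severe,
unbearable pain), mostly at scheduled nurse rounding times plus extra records
when a patient reports sudden pain. A CPE is a time bin whose recorded NRS is
≥ 4 — the usual indication for opioid rescue intervention. Because ward
routines and each patient's own pain dynamics repeat from day to day, the
next day's CPE timing is partly predictable from the recent record. This
package provides the full analysis pipeline for studying that predictability:

* a **synthetic cohort generator** that emulates the statistical structure of
  real hematology–oncology ward pain logs (circadian recording pattern,
  patient frailty, day-to-day persistence, acute multi-day episodes), so the
  pipeline is fully testable without access to restricted EMR data;
* **preprocessing**: τ-binning (max aggregation, zero imputation),
  midnight-anchored reshaping of an *n*-day admission into a (24/τ) × *n*
  day-matrix, CPE labelling, forecast-sample construction and a patient-level
  train/test split;
* **models**: six parameter-budget-matched sequence classifiers (RNN, LSTM,
  GRU, Bi-LSTM, CNN-LSTM, Transformer; three stacked blocks plus a dense
  sigmoid head, non-autoregressive — all 24/τ next-day probabilities in one
  forward pass) and a same-time-of-day **averaging base model**;
* **training**: prevalence-balanced cross entropy optimized by Adam under
  stochastic weight averaging (SWA);
* **evaluation**: Matthews correlation coefficient (MCC), AUROC and AUPRC,
  pooled over all bins, and a grid runner over input lengths × τ × model.

## The statistic at the core

Next-day prediction is a set of 24/τ independent binary classifications.
Because positives are rare at fine binning (≈6 % of 1-h bins vs ≈44.5 % of
12-h bins), models are compared by the Matthews correlation coefficient

```
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)) ∈ [−1, 1],
```

computed from the confusion matrix pooled over every bin of every test
sample (probabilities thresholded at 0.5). The balanced loss

```
L = −mean[ y·log q / (2p) + (1−y)·log(1−q) / (2(1−p)) ]
```

weights each class by its training prevalence *p* so both contribute equally
in expectation.

## Worked example

```python
from cpecast import (GeneratorConfig, ModelSpec, TrainConfig, build_model,
                     cohort_samples, cohort_summary, evaluate_model,
                     generate_cohort, split_cohort, train_model)

cohort = generate_cohort(GeneratorConfig(n_patients=200, seed=11))
s = cohort_summary(cohort, tau=1)
print(f"median records/day: {s['records_per_day_median']:.2f}")
print(f"median CPE/day:     {s['cpe_per_day_median']:.2f}")
print(f"CPE fraction (1-h bins): {s['cpe_bin_fraction']:.3f}")

train, test = split_cohort(cohort, test_fraction=0.2, seed=11)
tau, L = 12, 120
tr, te = cohort_samples(train, L, tau), cohort_samples(test, L, tau)

lstm = build_model(ModelSpec("LSTM", 12, L // tau, 24 // tau), seed=11)
train_model(lstm, tr, TrainConfig(epochs=300, seed=11))
res = evaluate_model(lstm, te, tau)
print(f"LSTM  MCC={res.mcc:.4f}  AUROC={res.auroc:.4f}  AUPRC={res.auprc:.4f}")

base = build_model(ModelSpec("Base", 0, L // tau, 24 // tau, n_blocks=0))
resb = evaluate_model(base, te, tau)
print(f"Base  MCC={resb.mcc:.4f}  AUROC={resb.auroc:.4f}  AUPRC={resb.auprc:.4f}")
```

prints

```
median records/day: 2.79
median CPE/day:     1.17
CPE fraction (1-h bins): 0.056
LSTM  MCC=0.3689  AUROC=0.7555  AUPRC=0.6429
Base  MCC=0.3277  AUROC=0.7189  AUPRC=0.5641
```

The cohort statistics sit at the calibrated ward values — a median of 2.79
NRS records and 1.17 CPE events per admission-day, with 5.6 % of 1-h bins
positive — and the trained LSTM clears the untrained same-time-of-day
averaging baseline on all three metrics at 120-h input and 12-h bins. The
run is fully deterministic given the seeds shown.

A command-line interface wraps the same pipeline:

```bash
cpecast generate --output cohort.csv          # synthetic cohort + provenance
cpecast run --output-dir runs --cells 120:12:LSTM,120:12:Base
cpecast report --results runs/results.csv --cohort cohort.csv
```

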