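"""MCC / AUROC / AUPRC scoring and the (input length x tau x model) grid.

Next-day CPE prediction is treated as independent per-bin binary
classification, so all bins of all test samples are pooled into a single
confusion matrix and a single ranking (micro pooling).  The Matthews
correlation coefficient is the headline score because the positive class is
rare at small tau; AUROC and AUPRC are the threshold-free companions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .models import ModelSpec, build_model, match_budgets
from .preprocessing import cohort_samples, samples_to_arrays
from .synthetic import AdmissionSeries
from .training import TrainConfig, train_model

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalResult:
    input_length_h: int
    tau: int
    architecture: str
    mcc: float
    auroc: float          # nan when the test bins are one-class
    auprc: float
    confusion: ConfusionCounts
    n_samples: int
    seed: int
    best: bool = field(default=False)
    second_best: bool = field(default=False)


def mcc(confusion: ConfusionCounts) -> float:
    """Matthews correlation coefficient from pooled confusion counts.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); any zero
    marginal makes the ratio indeterminate and is scored as 0 by convention.
    """
    if confusion.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = (float(confusion.tp), float(confusion.fp),
                      float(confusion.tn), float(confusion.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / sqrt(denom)


def binarize(probabilities: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Probability >= threshold -> 1 (the boundary counts as positive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly between 0 and 1")
    return (np.asarray(probabilities, dtype=float) >= threshold).astype(int)


def confusion_counts(targets: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    y = np.asarray(targets).astype(int).ravel()
    yhat = np.asarray(predictions).astype(int).ravel()
    if y.shape != yhat.shape:
        raise ValueError("targets and predictions differ in length")
    return ConfusionCounts(
        tp=int(((y == 1) & (yhat == 1)).sum()),
        fp=int(((y == 0) & (yhat == 1)).sum()),
        tn=int(((y == 0) & (yhat == 0)).sum()),
        fn=int(((y == 1) & (yhat == 0)).sum()),
    )


def ranking_metrics(targets: np.ndarray, probabilities: np.ndarray) -> tuple[float, float]:
    """(AUROC, AUPRC) pooled over all bins; (nan, nan) for one-class input.

    AUROC follows the rank / Mann-Whitney formulation with tie averaging;
    AUPRC is the step integration of the precision-recall curve.
    """
    y = np.asarray(targets).astype(int).ravel()
    q = np.asarray(probabilities, dtype=float).ravel()
    if y.min() == y.max():
        return float("nan"), float("nan")
    return float(roc_auc_score(y, q)), float(average_precision_score(y, q))


def evaluate_model(model, samples, tau: int, *, input_length_h: int = 0,
                   architecture: str = "", seed: int = 0,
                   threshold: float = DEFAULT_THRESHOLD) -> EvalResult:
    """Pool every bin of every test sample and score the three metrics."""
    if not samples:
        raise ValueError("no test samples")
    X, Y = samples_to_arrays(samples)
    probs = model.predict_proba(X)
    conf = confusion_counts(Y, binarize(probs, threshold))
    auroc, auprc = ranking_metrics(Y, probs)
    return EvalResult(
        input_length_h=input_length_h, tau=tau, architecture=architecture,
        mcc=mcc(conf), auroc=auroc, auprc=auprc, confusion=conf,
        n_samples=len(samples), seed=seed,
    )


def per_admission_results(model, cohort: list[AdmissionSeries], L: int, tau: int,
                          threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Case-report view: one row of metrics per admission (same machinery)."""
    rows = []
    for adm in cohort:
        samples = cohort_samples([adm], L, tau)
        if not samples:
            continue
        res = evaluate_model(model, samples, tau, input_length_h=L,
                             architecture="", threshold=threshold)
        rows.append({"admission_id": adm.admission_id, "mcc": res.mcc,
                     "auroc": res.auroc, "auprc": res.auprc,
                     "n_samples": res.n_samples})
    return pd.DataFrame(rows)


def _flag_best(results: list[EvalResult]) -> None:
    """Mark best and second-best MCC among trainable rows of each (L, tau)."""
    cells: dict[tuple[int, int], list[EvalResult]] = {}
    for r in results:
        if r.architecture != "Base":
            cells.setdefault((r.input_length_h, r.tau), []).append(r)
    for rows in cells.values():
        ranked = sorted(rows, key=lambda r: r.mcc, reverse=True)
        if ranked:
            ranked[0].best = True
        if len(ranked) > 1:
            ranked[1].second_best = True


def run_grid(train_cohort: list[AdmissionSeries], test_cohort: list[AdmissionSeries],
             input_lengths: tuple[int, ...], taus: tuple[int, ...],
             architectures: tuple[str, ...], train_config: TrainConfig,
             reference_width: int = 12, seed: int = 0,
             log_dir: str | Path | None = None) -> list[EvalResult]:
    """One EvalResult per (L, tau, architecture) cell, base model included.

    Cells whose test bins are one-class keep their MCC/confusion but report
    ranking metrics as nan; they are returned, never dropped.
    """
    if not input_lengths or not taus or not architectures:
        raise ValueError("grid must be nonempty")
    for arch in architectures:
        ModelSpec(arch, max(1, reference_width), 1, 1, n_blocks=0 if arch == "Base" else 3)
    results: list[EvalResult] = []
    for L in input_lengths:
        for tau in taus:
            specs = match_budgets(tuple(architectures), reference_width, L, tau)
            train_samples = cohort_samples(train_cohort, L, tau)
            test_samples = cohort_samples(test_cohort, L, tau)
            for arch in architectures:
                model = build_model(specs[arch], seed=seed)
                if arch != "Base":
                    cfg = TrainConfig(**{**vars(train_config), "seed": seed})
                    log_path = None
                    if log_dir is not None:
                        log_path = Path(log_dir) / \
                            f"train_L{L}_tau{tau}_{arch}_seed{seed}.log"
                    train_model(model, train_samples, cfg, log_path=log_path)
                results.append(evaluate_model(
                    model, test_samples, tau, input_length_h=L,
                    architecture=arch, seed=seed))
    _flag_best(results)
    return results


def results_to_frame(results: list[EvalResult]) -> pd.DataFrame:
    rows = [{
        "input_length_h": r.input_length_h, "tau": r.tau,
        "architecture": r.architecture, "mcc": r.mcc, "auroc": r.auroc,
        "auprc": r.auprc, "tp": r.confusion.tp, "fp": r.confusion.fp,
        "tn": r.confusion.tn, "fn": r.confusion.fn,
        "n_samples": r.n_samples, "seed": r.seed,
        "best": r.best, "second_best": r.second_best,
    } for r in results]
    return pd.DataFrame(rows)


def write_results(results: list[EvalResult], csv_path: str | Path,
                  json_path: str | Path | None = None) -> None:
    df = results_to_frame(results)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(df.to_dict(orient="records"), indent=2, default=float))


def pivot_mcc_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Table-style matrix: rows = input length x architecture, columns = tau."""
    if df.empty:
        raise ValueError("no results to pivot")
    piv = df.pivot_table(index=["input_length_h", "architecture"],
                         columns="tau", values="mcc", aggfunc="mean")
    return piv.sort_index()
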