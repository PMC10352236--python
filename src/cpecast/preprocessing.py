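"""From raw event logs to binned day-matrices, CPE labels and forecast samples.

The day is partitioned into 24/tau half-open bins [start, start+tau); multiple
records within a bin collapse to their maximum NRS, empty bins are imputed to
zero (patient considered pain-free).  Zero padding anchors every admission's
record to midnight at both ends, so an n-day admission becomes a
(24/tau) x n matrix with one column per calendar day.  A forecast sample
pairs the L hours of binned NRS preceding a forecast day (most recent last)
with that day's 24/tau binary CPE labels (binned NRS >= 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import MINUTES_PER_DAY, AdmissionSeries

CPE_THRESHOLD = 4
VALID_TAUS = (1, 2, 3, 4, 6, 8, 12)
VALID_INPUT_LENGTHS = (24, 72, 120)


@dataclass
class BinnedDayMatrix:
    """tau-binned, zero-imputed, midnight-anchored NRS values, one column per
    calendar day of the admission."""

    tau: int
    values: np.ndarray  # shape (24/tau, n_days), integer entries in [0, 10]

    def __post_init__(self):
        if self.tau not in VALID_TAUS:
            raise ValueError(f"tau must be one of {VALID_TAUS}")
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] != 24 // self.tau:
            raise ValueError("matrix shape must be (24/tau, n_days)")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 10):
            raise ValueError("binned NRS entries must lie in [0, 10]")

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    def flatten(self) -> np.ndarray:
        """Chronological vector form (inverse of the day-matrix reshape)."""
        return self.values.ravel(order="F")


@dataclass
class CpeLabels:
    tau: int
    values: np.ndarray  # binary, same shape as the labelled matrix

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("labels must be binary")


@dataclass
class ForecastSample:
    """L hours of binned NRS history plus the next day's binary CPE targets."""

    x: np.ndarray             # length L/tau, most recent bin last
    y: np.ndarray             # length 24/tau, binary
    admission_id: str = ""
    forecast_day_index: int = 0   # 1-based day column in the padded matrix


def _check_tau(tau: int) -> None:
    if tau not in VALID_TAUS:
        raise ValueError(f"tau must be a divisor of 24 excluding 24, got {tau}")


def bin_vector(admission: AdmissionSeries, tau: int) -> np.ndarray:
    """Pre-padding stage: max-aggregated bins from the first to the last bin
    overlapping the admission interval (chronological, zero-imputed)."""
    _check_tau(tau)
    bin_minutes = tau * 60
    first = admission.admit_minute // bin_minutes
    last = (admission.discharge_minute - 1) // bin_minutes
    vec = np.zeros(last - first + 1, dtype=int)
    for ev in admission.events:
        if not (admission.admit_minute <= ev.timestamp < admission.discharge_minute):
            raise ValueError("event outside admission interval")
        idx = ev.timestamp // bin_minutes - first
        vec[idx] = max(vec[idx], ev.nrs)
    return vec


def pad_and_reshape(vec: np.ndarray, tau: int,
                    admit_minute: int, discharge_minute: int) -> BinnedDayMatrix:
    """Extend the binned vector with zeros so the timeline starts and ends at
    0:00, then reshape to one column per calendar day."""
    _check_tau(tau)
    bin_minutes = tau * 60
    slots = 24 // tau
    first = admit_minute // bin_minutes
    n_days = -(-discharge_minute // MINUTES_PER_DAY)
    padded = np.zeros(slots * n_days, dtype=int)
    padded[first:first + len(vec)] = vec
    return BinnedDayMatrix(tau, padded.reshape(slots, n_days, order="F"))


def bin_series(admission: AdmissionSeries, tau: int) -> BinnedDayMatrix:
    """Bin an admission's events at tau and return the midnight-anchored
    day matrix (binning + zero-padding transformation in one step)."""
    vec = bin_vector(admission, tau)
    return pad_and_reshape(vec, tau, admission.admit_minute,
                           admission.discharge_minute)


def label_cpe(matrix: BinnedDayMatrix) -> CpeLabels:
    """Elementwise CPE indicator: binned NRS >= 4."""
    return CpeLabels(matrix.tau, (matrix.values >= CPE_THRESHOLD).astype(int))


def make_samples(matrix: BinnedDayMatrix, labels: CpeLabels, L: int,
                 admission_id: str = "") -> list[ForecastSample]:
    """One forecast sample per day with a full L-hour prior window.

    Forecast days run from day (L/24)+1 through day n of the padded matrix;
    earlier days lack a complete window and are skipped (windows never reach
    before the admission's first padded day, so inputs contain only real
    admission time).
    """
    if L % 24 or L <= 0:
        raise ValueError("input length L must be a positive multiple of 24 hours")
    if matrix.tau != labels.tau or matrix.values.shape != labels.values.shape:
        raise ValueError("matrix and labels disagree")
    n_hist = L // 24
    samples = []
    for day0 in range(n_hist, matrix.n_days):  # 0-based forecast day column
        x = matrix.values[:, day0 - n_hist:day0].ravel(order="F")
        y = labels.values[:, day0]
        samples.append(ForecastSample(x=x, y=y.copy(), admission_id=admission_id,
                                      forecast_day_index=day0 + 1))
    return samples


def cohort_samples(cohort: list[AdmissionSeries], L: int, tau: int) -> list[ForecastSample]:
    """Preprocess a whole cohort into forecast samples."""
    out: list[ForecastSample] = []
    for adm in cohort:
        mat = bin_series(adm, tau)
        out.extend(make_samples(mat, label_cpe(mat), L, adm.admission_id))
    return out


def samples_to_arrays(samples: list[ForecastSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.x for s in samples]).astype(float)
    Y = np.stack([s.y for s in samples]).astype(float)
    return X, Y


def split_cohort(cohort: list[AdmissionSeries], test_fraction: float,
                 seed: int) -> tuple[list[AdmissionSeries], list[AdmissionSeries]]:
    """Patient-level holdout split; every admission follows its patient."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    patients = sorted({adm.patient_id for adm in cohort})
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_test = max(1, round(len(patients) * test_fraction))
    n_test = min(n_test, len(patients) - 1)
    test_ids = {patients[i] for i in order[:n_test]}
    train = [adm for adm in cohort if adm.patient_id not in test_ids]
    test = [adm for adm in cohort if adm.patient_id in test_ids]
    return train, test


def filter_admissions(cohort: list[AdmissionSeries],
                      min_nonzero_records: int = 20) -> list[AdmissionSeries]:
    """Optional inclusion filter: keep admissions with enough nonzero records."""
    return [adm for adm in cohort
            if sum(ev.nrs > 0 for ev in adm.events) >= min_nonzero_records]


def write_samples_csv(samples: list[ForecastSample], path) -> None:
    """Columnar inspection dump: ids, forecast day, x..., y... per row."""
    import pandas as pd

    if not samples:
        raise ValueError("no samples to write")
    nx, ny = len(samples[0].x), len(samples[0].y)
    cols = (["admission_id", "forecast_day"]
            + [f"x{i}" for i in range(nx)] + [f"y{i}" for i in range(ny)])
    rows = [[s.admission_id, s.forecast_day_index, *s.x.tolist(), *s.y.tolist()]
            for s in samples]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
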