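"""Binning, midnight-anchored transformation, labels, samples and the split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpecast.preprocessing import (
    VALID_TAUS,
    BinnedDayMatrix,
    bin_series,
    bin_vector,
    cohort_samples,
    label_cpe,
    make_samples,
    pad_and_reshape,
    split_cohort,
)
from cpecast.synthetic import PainEvent

from conftest import make_admission


class TestBinning:
    def test_max_aggregation_within_bin(self):
        adm = make_admission([(0, 10, 15, 3), (0, 10, 40, 5)], n_days=1)
        mat = bin_series(adm, 1)
        assert mat.values[10, 0] == 5

    def test_empty_bin_imputed_zero(self):
        adm = make_admission([(0, 10, 15, 3)], n_days=1)
        assert bin_series(adm, 1).values[3, 0] == 0

    def test_single_event_two_bins_at_tau12(self):
        adm = make_admission([(0, 13, 0, 2)], n_days=1, admit_minute=0)
        mat = bin_series(adm, 12)
        assert mat.values[:, 0].tolist() == [0, 2]

    def test_tau_not_dividing_24_rejected(self):
        adm = make_admission([(0, 10, 0, 3)], n_days=1)
        with pytest.raises(ValueError):
            bin_series(adm, 5)

    def test_event_outside_admission_rejected(self):
        adm = make_admission([(0, 12, 0, 3)], n_days=1)
        adm.events.append(PainEvent("P1", "P1-A0", 3 * 1440, 5))
        with pytest.raises(ValueError):
            bin_vector(adm, 1)

    @pytest.mark.parametrize("tau", VALID_TAUS)
    def test_shape_is_24_over_tau_by_days(self, tau, small_cohort):
        adm = small_cohort[0]
        mat = bin_series(adm, tau)
        assert mat.values.shape == (24 // tau, adm.n_days)

    @pytest.mark.parametrize("tau1,tau2", [(t1, t2) for t1 in VALID_TAUS
                                           for t2 in VALID_TAUS
                                           if t2 % t1 == 0 and t1 != t2])
    def test_coarsening_consistency(self, tau1, tau2, small_cohort):
        """Binning at tau1 then max-pooling groups equals binning at tau2."""
        for adm in small_cohort[:5]:
            fine = bin_series(adm, tau1).values
            coarse = bin_series(adm, tau2).values
            k = tau2 // tau1
            pooled = np.maximum.reduceat(fine, np.arange(0, fine.shape[0], k), axis=0)
            assert np.array_equal(pooled, coarse)

    def test_cpe_fraction_nondecreasing_in_tau(self, small_cohort):
        fracs = []
        for tau in VALID_TAUS:
            num = den = 0
            for adm in small_cohort:
                lab = label_cpe(bin_series(adm, tau)).values
                num += lab.sum()
                den += lab.size
            fracs.append(num / den)
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestPadAndReshape:
    def test_five_complete_days(self):
        adm = make_admission([(0, 1, 0, 2)], n_days=5, admit_minute=0)
        assert bin_series(adm, 1).values.shape == (24, 5)

    def test_partial_first_day_padded_with_zeros(self):
        adm = make_admission([(0, 15, 0, 7)], n_days=2, admit_minute=14 * 60 + 30)
        mat = bin_series(adm, 1)
        assert mat.values[:14, 0].sum() == 0
        assert mat.values[15, 0] == 7

    def test_flatten_roundtrip(self):
        adm = make_admission([(0, 15, 0, 7), (1, 3, 30, 4)], n_days=2,
                             admit_minute=14 * 60)
        vec = bin_vector(adm, 2)
        mat = pad_and_reshape(vec, 2, adm.admit_minute, adm.discharge_minute)
        flat = mat.flatten()
        first = adm.admit_minute // 120
        assert np.array_equal(flat[first:first + len(vec)], vec)
        assert flat.size == 12 * adm.n_days

    def test_conserves_nonzero_multiset(self, small_cohort):
        for adm in small_cohort[:5]:
            vec = bin_vector(adm, 3)
            mat = pad_and_reshape(vec, 3, adm.admit_minute, adm.discharge_minute)
            assert sorted(vec[vec > 0]) == sorted(mat.values[mat.values > 0])


class TestLabels:
    @pytest.mark.parametrize("nrs,label", [(4, 1), (3, 0), (0, 0), (10, 1)])
    def test_threshold_at_four(self, nrs, label):
        mat = BinnedDayMatrix(12, np.array([[nrs], [0]]))
        assert label_cpe(mat).values[0, 0] == label

    def test_all_zero_matrix(self):
        mat = BinnedDayMatrix(1, np.zeros((24, 3), dtype=int))
        assert label_cpe(mat).values.sum() == 0


class TestMakeSamples:
    def test_three_days_L24_gives_two_samples(self):
        mat = BinnedDayMatrix(1, np.zeros((24, 3), dtype=int))
        samples = make_samples(mat, label_cpe(mat), 24)
        assert len(samples) == 2
        assert all(len(s.x) == 24 and len(s.y) == 24 for s in samples)
        assert [s.forecast_day_index for s in samples] == [2, 3]

    def test_six_days_L120_tau12_gives_one_sample(self):
        mat = BinnedDayMatrix(12, np.zeros((2, 6), dtype=int))
        samples = make_samples(mat, label_cpe(mat), 120)
        assert len(samples) == 1
        assert len(samples[0].x) == 10 and len(samples[0].y) == 2

    def test_single_day_yields_no_samples(self):
        mat = BinnedDayMatrix(1, np.zeros((24, 1), dtype=int))
        assert make_samples(mat, label_cpe(mat), 24) == []

    def test_window_precedes_target_chronologically(self):
        values = np.arange(48).reshape(24, 2, order="F") % 11
        mat = BinnedDayMatrix(1, values)
        s = make_samples(mat, label_cpe(mat), 24)[0]
        assert np.array_equal(s.x, values[:, 0])  # day 1 only, never day 2
        assert np.array_equal(s.y, (values[:, 1] >= 4).astype(int))

    @given(st.integers(2, 9), st.sampled_from([24, 72, 120]))
    @settings(max_examples=20, deadline=None)
    def test_sample_count_formula(self, n_days, L):
        mat = BinnedDayMatrix(12, np.zeros((2, n_days), dtype=int))
        samples = make_samples(mat, label_cpe(mat), L)
        assert len(samples) == max(0, n_days - L // 24)


class TestSplit:
    def test_patient_level_80_20(self, small_cohort):
        train, test = split_cohort(small_cohort, 0.2, seed=1)
        train_p = {a.patient_id for a in train}
        test_p = {a.patient_id for a in test}
        assert not train_p & test_p
        assert len(test_p) == round(30 * 0.2)
        assert len(train) + len(test) == len(small_cohort)

    def test_admissions_follow_their_patient(self, small_cohort):
        train, test = split_cohort(small_cohort, 0.3, seed=2)
        for side in (train, test):
            ids = {a.patient_id for a in side}
            assert all(a.patient_id in ids for a in side)
        # every admission of a multi-admission patient lands on one side
        by_patient: dict[str, set[str]] = {}
        for a in small_cohort:
            by_patient.setdefault(a.patient_id, set())
        test_p = {a.patient_id for a in test}
        for a in small_cohort:
            assert (a.patient_id in test_p) == (a in test)

    def test_same_seed_same_partition(self, small_cohort):
        a = split_cohort(small_cohort, 0.2, seed=7)
        b = split_cohort(small_cohort, 0.2, seed=7)
        assert [x.admission_id for x in a[1]] == [x.admission_id for x in b[1]]

    def test_too_few_patients_rejected(self, small_cohort):
        solo = [a for a in small_cohort if a.patient_id == small_cohort[0].patient_id]
        with pytest.raises(ValueError):
            split_cohort(solo, 0.2, seed=0)

    def test_bad_fraction_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            split_cohort(small_cohort, 1.0, seed=0)


def test_cohort_samples_targets_match_labels(small_cohort):
    samples = cohort_samples(small_cohort[:3], 24, 12)
    for adm in small_cohort[:3]:
        lab = label_cpe(bin_series(adm, 12)).values
        mine = [s for s in samples if s.admission_id == adm.admission_id]
        for s in mine:
            assert np.array_equal(s.y, lab[:, s.forecast_day_index - 1])
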