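"""MCC, ranking metrics, pooled evaluation and the experiment grid."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from cpecast.evaluation import (
    ConfusionCounts,
    binarize,
    confusion_counts,
    evaluate_model,
    mcc,
    pivot_mcc_matrix,
    ranking_metrics,
    results_to_frame,
    run_grid,
)
from cpecast.models import BaseModel, ModelSpec, build_model
from cpecast.preprocessing import ForecastSample, split_cohort
from cpecast.synthetic import GeneratorConfig, generate_cohort
from cpecast.training import TrainConfig


class TestMcc:
    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(tp=10, fp=0, tn=10, fn=0)) == 1.0

    def test_inverted_prediction(self):
        assert mcc(ConfusionCounts(tp=0, fp=10, tn=0, fn=10)) == -1.0

    def test_hand_case(self):
        got = mcc(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert got == pytest.approx(10 / np.sqrt(600))

    def test_zero_marginal_scored_zero(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, tn=5, fn=5)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mcc(ConfusionCounts(0, 0, 0, 0))

    def test_equals_phi_coefficient_on_random_instances(self, rng):
        """MCC from counts must match the Pearson correlation of the binary
        prediction/target vectors (sklearn as the independent route)."""
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            yhat = rng.integers(0, 2, size=n)
            ours = mcc(confusion_counts(y, yhat))
            ref = matthews_corrcoef(y, yhat)
            assert ours == pytest.approx(ref, abs=1e-12)


class TestBinarize:
    def test_boundary_counts_as_positive(self):
        assert binarize(np.array([0.5]), 0.5).tolist() == [1]

    def test_all_zero_probabilities(self):
        assert binarize(np.zeros(5)).sum() == 0

    def test_positive_count_nonincreasing_in_threshold(self, rng):
        q = rng.uniform(size=100)
        counts = [binarize(q, t).sum() for t in np.linspace(0.05, 0.95, 19)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros(2), 0.0)


def auroc_pair_counting(y, q):
    """Brute-force Mann-Whitney: wins + half-ties over all pos/neg pairs."""
    pos = q[y == 1]
    neg = q[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRankingMetrics:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        q = np.array([0.1, 0.2, 0.8, 0.9])
        auroc, auprc = ranking_metrics(y, q)
        assert auroc == 1.0 and auprc == 1.0

    def test_constant_scores_give_half_auroc(self):
        y = np.array([0, 1, 0, 1])
        auroc, _ = ranking_metrics(y, np.full(4, 0.3))
        assert auroc == pytest.approx(0.5)

    def test_six_bin_hand_case_matches_pair_counting(self):
        y = np.array([1, 0, 1, 0, 0, 1])
        q = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.2])
        auroc, _ = ranking_metrics(y, q)
        assert auroc == pytest.approx(auroc_pair_counting(y, q))

    def test_random_vectors_match_pair_counting(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 21))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            q = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # ties likely
            auroc, _ = ranking_metrics(y, q)
            assert auroc == pytest.approx(auroc_pair_counting(y, q), abs=1e-12)

    def test_one_class_reported_missing(self):
        auroc, auprc = ranking_metrics(np.ones(4), np.linspace(0, 1, 4))
        assert np.isnan(auroc) and np.isnan(auprc)

    def test_auroc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=60)
        y[0], y[1] = 0, 1
        q = rng.uniform(size=60)
        a1, _ = ranking_metrics(y, q)
        a2, _ = ranking_metrics(y, np.exp(3 * q) / (1 + np.exp(3 * q)))
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestEvaluateModel:
    def _samples(self, X, Y):
        return [ForecastSample(x=x, y=y) for x, y in zip(X, Y)]

    def test_pooled_counts_sum_to_bins(self, rng):
        X = rng.integers(0, 11, size=(7, 4)).astype(float)
        Y = rng.integers(0, 2, size=(7, 2))
        Y[0] = [0, 1]
        model = BaseModel(4, 2)
        res = evaluate_model(model, self._samples(X, Y), tau=12)
        assert res.confusion.total == 7 * 2

    def test_base_model_on_periodic_history_scores_unit_mcc(self):
        samples = [ForecastSample(x=np.tile([6.0, 0.0], 2), y=np.array([1, 0])),
                   ForecastSample(x=np.tile([0.0, 5.0], 2), y=np.array([0, 1]))]
        res = evaluate_model(BaseModel(4, 2), samples, tau=12)
        assert res.mcc == 1.0

    def test_constant_half_probability_predicts_all_positive(self):
        class Half:
            def predict_proba(self, X):
                return np.full((X.shape[0], 2), 0.5)

        samples = [ForecastSample(x=np.zeros(4), y=np.array([0, 1]))]
        res = evaluate_model(Half(), samples, tau=12)
        assert res.confusion.tn == 0 and res.confusion.fn == 0

    def test_pooled_metrics_match_hand_computation(self):
        """Two tau=12 samples with known outputs; pool by hand."""
        class Fixed:
            def predict_proba(self, X):
                return np.array([[0.9, 0.2], [0.6, 0.4]])

        samples = [ForecastSample(x=np.zeros(4), y=np.array([1, 0])),
                   ForecastSample(x=np.zeros(4), y=np.array([0, 0]))]
        res = evaluate_model(Fixed(), samples, tau=12)
        # predictions at 0.5: [1,0,1,0]; targets [1,0,0,0]
        assert (res.confusion.tp, res.confusion.fp,
                res.confusion.tn, res.confusion.fn) == (1, 1, 2, 0)
        assert res.mcc == pytest.approx(
            (1 * 2 - 1 * 0) / np.sqrt(2 * 1 * 3 * 2))
        assert res.auroc == pytest.approx(auroc_pair_counting(
            np.array([1, 0, 0, 0]), np.array([0.9, 0.2, 0.6, 0.4])))

    def test_evaluation_is_pure(self, rng):
        X = rng.integers(0, 11, size=(5, 4)).astype(float)
        Y = rng.integers(0, 2, size=(5, 2))
        Y[0] = [0, 1]
        model = BaseModel(4, 2)
        r1 = evaluate_model(model, self._samples(X, Y), tau=12)
        r2 = evaluate_model(model, self._samples(X, Y), tau=12)
        assert r1.mcc == r2.mcc and r1.auroc == r2.auroc


@pytest.fixture(scope="module")
def tiny_split():
    cohort = generate_cohort(GeneratorConfig(n_patients=14, seed=4))
    return split_cohort(cohort, 0.25, seed=4)


class TestGrid:
    def test_grid_cardinality(self, tiny_split):
        train, test = tiny_split
        results = run_grid(train, test, (24,), (12,), ("LSTM", "Base"),
                           TrainConfig(epochs=3, swa_start_epoch=1, seed=0), seed=0)
        assert len(results) == 2
        assert {r.architecture for r in results} == {"LSTM", "Base"}

    def test_best_flag_marks_trainable_rows_only(self, tiny_split):
        train, test = tiny_split
        results = run_grid(train, test, (24,), (12,), ("LSTM", "RNN", "Base"),
                           TrainConfig(epochs=3, swa_start_epoch=1, seed=0), seed=0)
        trainable = [r for r in results if r.architecture != "Base"]
        assert sum(r.best for r in trainable) == 1
        assert sum(r.second_best for r in trainable) == 1
        assert not any(r.best or r.second_best
                       for r in results if r.architecture == "Base")

    def test_results_frame_and_pivot(self, tiny_split):
        train, test = tiny_split
        results = run_grid(train, test, (24,), (12,), ("LSTM", "Base"),
                           TrainConfig(epochs=2, swa_start_epoch=1, seed=0), seed=0)
        df = results_to_frame(results)
        assert len(df) == 2
        piv = pivot_mcc_matrix(df)
        assert piv.shape == (2, 1)

    def test_empty_grid_rejected(self, tiny_split):
        train, test = tiny_split
        with pytest.raises(ValueError):
            run_grid(train, test, (), (12,), ("LSTM",),
                     TrainConfig(epochs=2, swa_start_epoch=1, seed=0))

    def test_unknown_architecture_rejected_before_training(self, tiny_split):
        train, test = tiny_split
        with pytest.raises(ValueError):
            run_grid(train, test, (24,), (12,), ("LSTM", "Oracle"),
                     TrainConfig(epochs=2, swa_start_epoch=1, seed=0))
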