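"""Model search, evaluation metrics, best-model selection, prediction format."""

import numpy as np
import pandas as pd
import pytest

import edaffect as ea
from edaffect.models import FOUR_CLASS, EvaluationReport
from edaffect.selection import FeatureRanking

SMALL_SEARCH = ea.SearchSpace(algorithms=("KNN", "RF"), n_features_grid=(5, 15), n_iter=2)
SMALL_CV = ea.CVConfig(folds=5, repeats=2)


def _separable_table(n_per_class=20, noise=0.01, seed=0, shuffle_labels=False):
    """Feature table where one column encodes the quadrant index plus
    tiny noise — linearly separable by construction."""
    rng = np.random.default_rng(seed)
    labels, mean_col = [], []
    for k, quad in enumerate(ea.QUADRANT_ORDER):
        labels += [quad] * n_per_class
        mean_col += list(k / 3.0 + rng.normal(0, noise, n_per_class))
    data = pd.DataFrame(
        rng.uniform(0, 1, (len(labels), 15)), columns=list(ea.FEATURE_NAMES)
    )
    data["Mean"] = np.clip(mean_col, 0, 1)
    labels = pd.Series(labels)
    if shuffle_labels:
        labels = labels.sample(frac=1.0, random_state=seed).reset_index(drop=True)
    return ea.FeatureTable(data=data, labels=labels, normalized=True)


def brute_force_confusion(y_true, y_pred):
    tp = sum(t == "positive" and p == "positive" for t, p in zip(y_true, y_pred))
    fp = sum(t == "rest" and p == "positive" for t, p in zip(y_true, y_pred))
    fn = sum(t == "positive" and p == "rest" for t, p in zip(y_true, y_pred))
    tn = sum(t == "rest" and p == "rest" for t, p in zip(y_true, y_pred))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / len(y_true)
    return accuracy, f1, precision, recall


class TestEvaluate:
    def test_hand_computed_confusion(self):
        y_true = ["positive"] * 4 + ["rest"] * 6
        y_pred = ["positive", "positive", "positive", "rest", "positive", "rest", "rest", "rest", "rest", "rest"]
        # TP=3 FP=1 FN=1 TN=5
        report = ea.evaluate(y_pred, y_true, architecture="Happy")
        assert report.precision == pytest.approx(0.75)
        assert report.recall == pytest.approx(0.75)
        assert report.f1 == pytest.approx(0.75)
        assert report.accuracy == pytest.approx(0.8)

    def test_all_correct_is_perfect(self):
        y = ["positive", "rest"] * 5
        report = ea.evaluate(y, y, architecture="Happy")
        assert (report.accuracy, report.f1, report.precision, report.recall) == (1.0, 1.0, 1.0, 1.0)

    def test_no_positive_predictions_degenerate_convention(self):
        y_true = ["positive"] * 3 + ["rest"] * 3
        y_pred = ["rest"] * 6
        report = ea.evaluate(y_pred, y_true, architecture="Happy")
        assert report.precision == 0.0 and report.recall == 0.0 and report.f1 == 0.0

    def test_agrees_with_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            y_true = rng.choice(["positive", "rest"], n).tolist()
            y_pred = rng.choice(["positive", "rest"], n).tolist()
            report = ea.evaluate(y_pred, y_true, architecture="Happy")
            acc, f1, prec, rec = brute_force_confusion(y_true, y_pred)
            assert report.accuracy == pytest.approx(acc)
            assert report.f1 == pytest.approx(f1)
            assert report.precision == pytest.approx(prec)
            assert report.recall == pytest.approx(rec)

    def test_binary_f1_is_harmonic_mean_of_reported_precision_recall(self):
        rng = np.random.default_rng(12)
        y_true = rng.choice(["positive", "rest"], 50).tolist()
        y_pred = rng.choice(["positive", "rest"], 50).tolist()
        r = ea.evaluate(y_pred, y_true, architecture="Sad")
        if r.precision + r.recall > 0:
            assert r.f1 == pytest.approx(2 * r.precision * r.recall / (r.precision + r.recall), abs=1e-6)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ea.evaluate([], [])

    def test_four_class_weighted_metrics(self):
        y_true = [q.value for q in ea.QUADRANT_ORDER] * 3
        y_pred = list(y_true)
        y_pred[0] = "Sad"
        report = ea.evaluate(y_pred, y_true, architecture=FOUR_CLASS)
        assert report.accuracy == pytest.approx(11 / 12)
        assert 0 < report.f1 <= 1


class TestSelectBest:
    def test_picks_highest_f1_from_published_style_row(self):
        f1s = {"KNN": 0.569, "RF": 0.641, "MLP": 0.525, "LSVC": 0.602, "GB": 0.584}
        reports = [
            EvaluationReport(accuracy=0.7, f1=f1, precision=f1, recall=f1, algorithm=alg)
            for alg, f1 in f1s.items()
        ]
        assert ea.select_best(reports).algorithm == "RF"
        assert ea.select_best(reports).f1 == pytest.approx(0.641)

    def test_single_report_is_returned(self):
        r = EvaluationReport(0.5, 0.5, 0.5, 0.5, algorithm="KNN")
        assert ea.select_best([r]) is r

    def test_tie_broken_by_accuracy(self):
        a = EvaluationReport(accuracy=0.9, f1=0.6, precision=0.6, recall=0.6, algorithm="GB")
        b = EvaluationReport(accuracy=0.7, f1=0.6, precision=0.6, recall=0.6, algorithm="KNN")
        assert ea.select_best([a, b]) is a

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ea.select_best([])


class TestPredictionFormat:
    def test_probability_vector_maps_to_happy_flags(self):
        pred = ea.EmotionPrediction.from_probabilities((0.84, 0.18, 0.12, 0.06), threshold=0.5)
        assert pred.flags == (True, False, False, False)

    def test_streaming_example_vector(self):
        pred = ea.EmotionPrediction.from_probabilities((0.71, 0.03, 0.13, 0.33), threshold=0.5)
        assert pred.flags == (True, False, False, False)

    def test_all_probabilities_below_threshold(self):
        pred = ea.EmotionPrediction.from_probabilities((0.4, 0.3, 0.2, 0.1), threshold=0.5)
        assert pred.flags == (False, False, False, False)

    def test_flags_consistent_with_threshold_invariant(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            probs = rng.uniform(0, 1, 4)
            pred = ea.EmotionPrediction.from_probabilities(probs, threshold=0.5)
            assert all(f == (p >= 0.5) for f, p in zip(pred.flags, pred.probabilities))


def _full_ranking():
    return FeatureRanking([(n, float(15 - i)) for i, n in enumerate(ea.FEATURE_NAMES)], source="anova_f")


class TestTrainAndTune:
    def test_separable_table_reaches_high_binary_f1(self):
        table = _separable_table(seed=1)
        for quad in ea.QUADRANT_ORDER:
            model = ea.train_and_tune(
                table, _full_ranking(), architecture=quad.value, search=SMALL_SEARCH, cv=SMALL_CV, seed=3
            )
            assert model.report.f1 >= 0.95, quad

    def test_permuted_labels_far_below_separable_performance(self):
        table = _separable_table(seed=2, shuffle_labels=True)
        model = ea.train_and_tune(
            table, _full_ranking(), architecture="Happy", search=SMALL_SEARCH, cv=SMALL_CV, seed=3
        )
        assert model.report.f1 < 0.8

    def test_same_seed_reproduces_spec_and_metrics(self):
        table = _separable_table(seed=4)
        kwargs = dict(architecture="Sad", search=SMALL_SEARCH, cv=SMALL_CV, seed=9)
        m1 = ea.train_and_tune(table, _full_ranking(), **kwargs)
        m2 = ea.train_and_tune(table, _full_ranking(), **kwargs)
        assert m1.spec == m2.spec
        assert m1.report == m2.report

    def test_stratification_error_on_tiny_class(self):
        table = _separable_table(n_per_class=3)
        with pytest.raises(ValueError, match="stratified"):
            ea.train_and_tune(table, _full_ranking(), architecture=FOUR_CLASS, search=SMALL_SEARCH, cv=SMALL_CV)

    def test_prediction_contract_end_to_end(self):
        table = _separable_table(seed=5)
        models = {
            q: ea.train_and_tune(
                table,
                _full_ranking(),
                architecture=q.value,
                search=ea.SearchSpace(algorithms=("RF",), n_features_grid=(5,), n_iter=1),
                cv=ea.CVConfig(folds=5, repeats=1),
                seed=1,
            )
            for q in ea.QUADRANT_ORDER
        }
        x = table.data.iloc[0]
        pred = ea.predict(models, x, threshold=0.5)
        assert isinstance(pred, ea.EmotionPrediction)
        assert len(pred.probabilities) == 4
        assert all(0.0 <= p <= 1.0 for p in pred.probabilities)

    def test_unnormalized_input_rejected_at_predict(self):
        table = _separable_table(seed=6)
        model = ea.train_and_tune(
            table,
            _full_ranking(),
            architecture=FOUR_CLASS,
            search=ea.SearchSpace(algorithms=("KNN",), n_features_grid=(5,), n_iter=1),
            cv=ea.CVConfig(folds=5, repeats=1),
            seed=1,
        )
        bad = table.data.iloc[0] * 100.0 + 5.0
        with pytest.raises(ValueError, match="normalized"):
            ea.predict(model, bad)

    def test_lsvc_probability_wrapper_emits_probabilities(self):
        table = _separable_table(seed=7)
        model = ea.train_and_tune(
            table,
            _full_ranking(),
            architecture="Happy",
            search=ea.SearchSpace(algorithms=("LSVC",), n_features_grid=(5,), n_iter=2),
            cv=ea.CVConfig(folds=5, repeats=1),
            seed=1,
        )
        pred = ea.predict({q: model for q in ea.QUADRANT_ORDER}, table.data.iloc[0])
        assert all(0.0 <= p <= 1.0 for p in pred.probabilities)
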