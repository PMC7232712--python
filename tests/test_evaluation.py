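"""Point metrics, ROC/PR curves and the cross-validation harness."""

import numpy as np
import pandas as pd
import pytest

from negsel.evaluation import (
    ClassifierSpec,
    ConfusionCounts,
    balance_experiment,
    compute_metrics,
    confusion_from_predictions,
    crossvalidate,
    make_classifier,
    pr_curve_points,
    roc_curve_points,
)
from negsel.features import CHANNELS


def make_frame(q_pos, q_neg, n_pos, n_neg, rng=None):
    """Feature frame with one informative level per class (plus optional noise)."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_pos):
        rows.append(["p", f"s{i}"] + [q_pos + 0.01 * rng.random() for _ in CHANNELS] + ["positive"])
    for i in range(n_neg):
        rows.append(["n", f"s{i}"] + [q_neg + 0.01 * rng.random() for _ in CHANNELS] + ["negative"])
    cols = ["drug", "side_effect"] + [f"q_{c}" for c in CHANNELS] + ["label"]
    return pd.DataFrame(rows, columns=cols)


class TestMetrics:
    # hand-evaluated confusion tables (numerators/denominators worked on paper)
    HAND_CASES = [
        (ConfusionCounts(90, 40, 10, 10),
         dict(SN=0.9, SP=0.8, ACC=13 / 15, MCC=0.7, Precision=0.9, F1=0.9)),
        (ConfusionCounts(50, 50, 0, 0),
         dict(SN=1.0, SP=1.0, ACC=1.0, MCC=1.0, Precision=1.0, F1=1.0)),
        (ConfusionCounts(25, 25, 25, 25),
         dict(SN=0.5, SP=0.5, ACC=0.5, MCC=0.0, Precision=0.5, F1=0.5)),
        (ConfusionCounts(8, 2, 3, 7),
         # MCC = (16-21)/sqrt(9*5*15*11) = -5/sqrt(7425)
         dict(SN=0.8 / 1.5, SP=0.4, ACC=0.5, MCC=-5 / np.sqrt(7425),
              Precision=8 / 11, F1=2 * (8 / 11) * (8 / 15) / (8 / 11 + 8 / 15))),
        (ConfusionCounts(1, 97, 1, 1),
         # MCC = (97-1)/sqrt(98*98*2*2) = 96/196
         dict(SN=0.5, SP=97 / 98, ACC=0.98, MCC=96 / 196, Precision=0.5, F1=0.5)),
    ]

    @pytest.mark.parametrize("counts,expected", HAND_CASES)
    def test_hand_computed_confusion_tables(self, counts, expected):
        got = compute_metrics(counts).as_dict()
        for name, value in expected.items():
            assert got[name] == pytest.approx(value, abs=1e-12), name

    def test_zero_denominator_yields_zero_and_flag(self):
        metrics = compute_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert metrics.sn == 0.0 and metrics.mcc == 0.0
        assert "SN" in metrics.flagged and "MCC" in metrics.flagged

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_confusion_recount_matches_direct_construction(self):
        labels = ["positive", "positive", "negative", "negative", "positive"]
        predicted = [True, False, True, False, True]
        counts = confusion_from_predictions(labels, predicted)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (2, 1, 1, 1)


def mann_whitney_auc(scores, labels):
    """Concordant-pair oracle: ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == "positive"]
    neg = [s for s, l in zip(scores, labels) if l == "negative"]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCurves:
    def test_perfect_ranking(self):
        labels = ["positive", "positive", "negative", "negative"]
        assert roc_curve_points([0.9, 0.8, 0.7, 0.6], labels).area == pytest.approx(1.0)
        assert pr_curve_points([0.9, 0.8, 0.7, 0.6], labels).area == pytest.approx(1.0)

    def test_mixed_ranking_concordance(self):
        labels = ["positive", "negative", "positive", "negative"]
        assert roc_curve_points([0.9, 0.8, 0.2, 0.1], labels).area == pytest.approx(0.75)

    def test_all_ties_give_chance_roc_and_prevalence_pr(self):
        labels = ["positive", "negative", "positive", "negative"]
        assert roc_curve_points([0.3] * 4, labels).area == pytest.approx(0.5)
        assert pr_curve_points([0.3] * 4, labels).area == pytest.approx(0.5)

    def test_mixed_pr_area_against_exhaustive_threshold_oracle(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = ["positive", "negative", "positive", "negative"]
        # independent enumeration of (recall, precision) at every threshold
        points = [(0.0, 1.0)]
        for t in sorted(set(scores), reverse=True):
            tp = sum(1 for s, l in zip(scores, labels) if s >= t and l == "positive")
            fp = sum(1 for s, l in zip(scores, labels) if s >= t and l == "negative")
            points.append((tp / 2, tp / (tp + fp)))
        expected = sum(
            (x2 - x1) * (y1 + y2) / 2
            for (x1, y1), (x2, y2) in zip(points, points[1:])
        )
        assert pr_curve_points(scores, labels).area == pytest.approx(expected)
        assert expected == pytest.approx(19 / 24)

    @pytest.mark.parametrize("seed", range(8))
    def test_roc_area_equals_mann_whitney_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # deliberate ties
        labels = ["positive" if rng.random() < 0.4 else "negative" for _ in range(n)]
        if "positive" not in labels or "negative" not in labels:
            pytest.skip("degenerate draw")
        assert roc_curve_points(scores, labels).area == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12
        )

    def test_roc_matches_reference_implementation(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.random(200)
        y = rng.integers(0, 2, size=200)
        labels = ["positive" if v else "negative" for v in y]
        assert roc_curve_points(scores, labels).area == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_points([0.1, 0.2], ["positive", "positive"])
        with pytest.raises(ValueError):
            pr_curve_points([0.1, 0.2], ["negative", "negative"])


class TestCrossValidate:
    def test_separable_data_classified_perfectly(self):
        frame = make_frame(0.9, 0.1, 60, 60)
        result = crossvalidate(frame, ClassifierSpec("rf", seed=0), k=5, seed=1)
        assert result.metrics.acc == 1.0
        assert result.roc.area == 1.0

    def test_shuffled_labels_give_near_zero_mcc(self):
        rng = np.random.default_rng(5)
        n = 1000
        rows = []
        for i in range(2 * n):
            label = "positive" if i < n else "negative"
            rows.append(["d", "s"] + list(rng.random(5)) + [label])
        cols = ["drug", "side_effect"] + [f"q_{c}" for c in CHANNELS] + ["label"]
        frame = pd.DataFrame(rows, columns=cols).sample(frac=1, random_state=1)
        result = crossvalidate(frame, ClassifierSpec("rf", seed=0), k=5, seed=2)
        assert abs(result.metrics.mcc) < 0.1

    def test_same_seed_gives_identical_folds_across_families(self):
        frame = make_frame(0.8, 0.2, 40, 40)
        rf = crossvalidate(frame, ClassifierSpec("rf", seed=0), k=4, seed=9)
        svm = crossvalidate(frame, ClassifierSpec("svm", seed=0), k=4, seed=9)
        assert np.array_equal(rf.fold_assignment, svm.fold_assignment)
        rf2 = crossvalidate(frame, ClassifierSpec("rf", seed=0), k=4, seed=9)
        assert np.array_equal(rf.scores, rf2.scores)

    def test_too_few_minority_samples_is_a_stratification_error(self):
        frame = make_frame(0.9, 0.1, 3, 40)
        with pytest.raises(ValueError, match="stratify"):
            crossvalidate(frame, ClassifierSpec("rf"), k=5)

    def test_classifier_families_resolve(self):
        for family in ("rf", "svm", "ann", "tree-ensemble"):
            assert make_classifier(ClassifierSpec(family)) is not None
        with pytest.raises(ValueError):
            make_classifier(ClassifierSpec("boosted-stumps"))


class TestBalanceExperiment:
    def test_mode_sizes_and_determinism(self):
        pos = make_frame(0.9, 0.1, 30, 0).iloc[:30]
        neg = make_frame(0.9, 0.1, 0, 90).iloc[:90]
        balanced = balance_experiment(
            pos, neg, mode="1x", n_repeats=2, k=3, seed=4
        )
        for result in balanced:
            assert sum(1 for l in result.labels if l == "negative") == 30
        imbalanced = balance_experiment(pos, neg, mode="2x", n_repeats=2, k=3, seed=4)
        for result in imbalanced:
            assert sum(1 for l in result.labels if l == "negative") == 60
        again = balance_experiment(pos, neg, mode="1x", n_repeats=2, k=3, seed=4)
        for a, b in zip(balanced, again):
            assert np.array_equal(a.scores, b.scores)

    def test_all_mode_uses_every_negative_once(self):
        pos = make_frame(0.9, 0.1, 20, 0).iloc[:20]
        neg = make_frame(0.9, 0.1, 0, 50).iloc[:50]
        (result,) = balance_experiment(pos, neg, mode="all", k=3, seed=0)
        assert sum(1 for l in result.labels if l == "negative") == 50

    def test_insufficient_negatives_error_states_requirement(self):
        pos = make_frame(0.9, 0.1, 30, 0).iloc[:30]
        neg = make_frame(0.9, 0.1, 0, 10).iloc[:10]
        with pytest.raises(ValueError, match="60"):
            balance_experiment(pos, neg, mode="2x", k=3)
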