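"""Evaluation battery: selection, confusion metrics, ROC, McNemar, grid."""

import numpy as np
import pytest
from sklearn.metrics import roc_curve
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

import twolayer as tl
from twolayer.evaluation import (decide_batch, evaluate_decisions,
                                 round_half_up_percent)

# Published per-class one-vs-rest confusion counts for the six-category
# behavior problem (best scaled-conjugate-gradient network, all 5396
# counted trials) with their tabulated percentages.
NET1_ROWS = [
    # class, tp, fp, fn, tn, fpr%, tpr%, precision%, accuracy%
    (1, 1017, 33, 8, 4338, 0.8, 99.2, 96.9, 99.2),
    (2, 471, 4, 4, 4917, 0.1, 99.2, 99.2, 99.9),
    (3, 279, 2, 2, 5113, 0.0, 99.3, 99.3, 99.9),
    (4, 1828, 28, 8, 3532, 0.8, 99.6, 98.5, 99.3),
    (5, 1545, 19, 4, 3828, 0.5, 99.7, 98.8, 99.6),
    (6, 162, 12, 72, 5150, 0.2, 69.2, 93.1, 98.4),
]

# Artifact/signal confusion counts of the best component classifier.
NET1B_ROWS = [
    ("artifact", 967, 49, 39, 577, 7.8, 96.1, 95.2, 94.6),
    ("signal", 577, 39, 49, 967, 3.9, 92.2, 93.7, 94.6),
]


class TestSelectCategory:
    def test_confident_probability_selected(self):
        decision = tl.select_category([0.9, 0.02, 0.02, 0.02, 0.02, 0.02], 0.17)
        assert decision.selected == 1 and not decision.missed

    def test_uniform_six_class_vector_is_missed(self):
        # chance level 1/6 = 16.66% sits below the 0.17 threshold
        decision = tl.select_category(np.full(6, 1 / 6), 0.17)
        assert decision.missed

    def test_tie_broken_toward_lowest_class(self):
        decision = tl.select_category([0.4, 0.4, 0.2, 0, 0, 0], 0.17)
        assert decision.selected == 1

    def test_invalid_vector_rejected(self):
        with pytest.raises(ValueError):
            tl.select_category([0.5, 0.4], 0.17)

    def test_count_missed(self):
        confident = np.tile([0.9, 0.1], (5, 1))
        uniform = np.full((3, 2), 0.5)
        decisions = decide_batch(np.vstack([confident, uniform]), 0.55)
        assert tl.count_missed(decisions) == 3


class TestConfusionCounts:
    def test_perfect_predictions_have_no_errors(self):
        counts = tl.confusion_counts([1, 2, 3], [1, 2, 3], 3)
        assert np.all(counts.fp == 0) and np.all(counts.fn == 0)

    def test_hand_enumerated_two_class_case(self):
        counts = tl.confusion_counts([1, 1, 2], [1, 2, 2], 2)
        assert (counts.tp[0], counts.fn[0], counts.fp[0], counts.tn[0]) == (1, 1, 0, 1)

    def test_per_class_totals_conserved(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(1, 5, 50)
        pred = rng.integers(1, 5, 50)
        counts = tl.confusion_counts(truth, pred, 4)
        totals = counts.tp + counts.fp + counts.fn + counts.tn
        assert np.all(totals == 50)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            tl.confusion_counts([1, 5], [1, 2], 4)


class TestMetrics:
    @pytest.mark.parametrize("row", NET1_ROWS,
                             ids=[f"class{r[0]}" for r in NET1_ROWS])
    def test_six_category_published_rows_reproduce(self, row):
        _, tp, fp, fn, tn, fpr, tpr, precision, accuracy = row
        counts = tl.ConfusionCounts(*(np.array([v]) for v in (tp, fp, fn, tn)))
        metrics = tl.metrics_from_counts(counts).iloc[0]
        assert metrics["fpr_pct"] == fpr
        assert metrics["tpr_pct"] == tpr
        assert metrics["precision_pct"] == precision
        assert metrics["accuracy_pct"] == accuracy

    @pytest.mark.parametrize("row", NET1B_ROWS, ids=[r[0] for r in NET1B_ROWS])
    def test_artifact_signal_published_rows_reproduce(self, row):
        _, tp, fp, fn, tn, fpr, tpr, precision, accuracy = row
        counts = tl.ConfusionCounts(*(np.array([v]) for v in (tp, fp, fn, tn)))
        metrics = tl.metrics_from_counts(counts).iloc[0]
        assert (metrics["fpr_pct"], metrics["tpr_pct"],
                metrics["precision_pct"], metrics["accuracy_pct"]) == (
                    fpr, tpr, precision, accuracy)

    def test_perfect_classifier(self):
        counts = tl.ConfusionCounts(np.array([10]), np.array([0]),
                                    np.array([0]), np.array([90]))
        metrics = tl.metrics_from_counts(counts).iloc[0]
        assert metrics["precision_pct"] == 100.0 and metrics["fpr_pct"] == 0.0

    def test_zero_denominator_gives_nan(self):
        counts = tl.ConfusionCounts(np.array([0]), np.array([0]),
                                    np.array([5]), np.array([5]))
        assert np.isnan(tl.metrics_from_counts(counts).iloc[0]["precision_pct"])

    def test_rate_identities_on_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 200, 4)
            precision = tp / (tp + fp) * 100
            tpr = tp / (tp + fn) * 100
            fnr = fn / (tp + fn) * 100
            tnr = tn / (fp + tn) * 100
            accuracy = (tp + tn) / (tp + fp + fn + tn) * 100
            assert np.isclose(tpr + fnr, 100.0)
            pos_weight = (tp + fn) / (tp + fp + fn + tn)
            assert np.isclose(accuracy,
                              pos_weight * tpr + (1 - pos_weight) * tnr)
            assert 0 <= precision <= 100

    def test_half_up_rounding(self):
        assert round_half_up_percent(1, 800) == 0.1   # 0.125 -> 0.1
        assert round_half_up_percent(3, 2000) == 0.2  # 0.15 exact half -> up
        assert round_half_up_percent(1, 1000) == 0.1  # 0.1 exact


class TestRoc:
    def test_perfect_separation_passes_through_top_left(self):
        points = tl.roc_points([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert (0.0, 1.0) in points

    def test_constant_scores_give_diagonal(self):
        points = tl.roc_points([0.5] * 6, [True, False] * 3)
        assert points == [(0.0, 0.0), (1.0, 1.0)]

    def test_hand_enumerated_curve(self):
        points = tl.roc_points([0.9, 0.8, 0.4, 0.1], [True, True, False, False])
        assert points == [(0.0, 0.0), (0.0, 0.5), (0.0, 1.0),
                          (0.5, 1.0), (1.0, 1.0)]

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            tl.roc_points([0.5, 0.6], [True, True])

    def test_fpr_monotone_on_random_scores(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = rng.integers(4, 40)
            scores = rng.normal(size=n)
            truth = rng.integers(0, 2, n).astype(bool)
            if truth.all() or not truth.any():
                continue
            fprs = [p[0] for p in tl.roc_points(scores, truth)]
            assert all(b >= a for a, b in zip(fprs, fprs[1:]))


class TestMcNemar:
    def test_published_discordant_pair(self):
        """3 vs 10 missed trials: chi-square 3.769, p just above 0.05."""
        statistic = tl.mcnemar_statistic(3, 10)
        assert round(statistic, 3) == 3.769
        assert abs(tl.mcnemar_pvalue(statistic) - 0.052) <= 5e-4

    def test_symmetric_discordants_give_zero(self):
        assert tl.mcnemar_statistic(5, 5) == 0.0

    def test_no_discordant_pairs_rejected(self):
        with pytest.raises(ValueError):
            tl.mcnemar_statistic(0, 0)

    def test_no_continuity_correction(self):
        # with correction the published 3.769 would have been 2.769
        assert np.isclose(tl.mcnemar_statistic(3, 10), 49 / 13)

    def test_discordant_counts_from_correctness(self):
        a = [True, True, False, True, False]
        b = [True, False, True, True, False]
        assert tl.discordant_counts(a, b) == (1, 1)


class TestOracleEquivalence:
    """Confusion counts and ROC points match scikit-learn / statsmodels."""

    def test_confusion_and_roc_match_sklearn(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(6, 30))
            truth = rng.integers(1, 4, n)
            pred = rng.integers(1, 4, n)
            counts = tl.confusion_counts(truth, pred, 3)
            for k in range(1, 4):
                t = truth == k
                p = pred == k
                assert counts.tp[k - 1] == np.sum(t & p)
                assert counts.fp[k - 1] == np.sum(~t & p)
                assert counts.fn[k - 1] == np.sum(t & ~p)
                assert counts.tn[k - 1] == np.sum(~t & ~p)
            scores = rng.normal(size=n)
            binary = truth == 1
            if binary.all() or not binary.any():
                continue
            ours = np.array(tl.roc_points(scores, binary))
            fpr, tpr, _ = roc_curve(binary, scores, drop_intermediate=False)
            theirs = np.column_stack([fpr, tpr])
            assert ours.shape == theirs.shape
            assert np.allclose(ours, theirs)

    def test_mcnemar_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            b, c = rng.integers(0, 30, 2)
            if b + c == 0:
                continue
            table = [[10, b], [c, 10]]
            reference = sm_mcnemar(table, exact=False, correction=False)
            assert np.isclose(tl.mcnemar_statistic(b, c), reference.statistic)
            assert np.isclose(tl.mcnemar_pvalue(tl.mcnemar_statistic(b, c)),
                              reference.pvalue)


def small_grid_problem():
    """Small well-separated 3-class problem for grid tests."""
    rng = np.random.default_rng(5)
    centers = np.array([[3.0, 0.0], [-3.0, 0.0], [0.0, 3.0]])
    labels = rng.integers(1, 4, 120)
    X = centers[labels - 1] + 0.4 * rng.normal(size=(120, 2))
    X_new = centers[rng.integers(0, 3, 30)] + 0.4 * rng.normal(size=(30, 2))
    return X, labels, X_new


class TestModelSelectionGrid:
    def test_grid_shape_and_ranges(self):
        X, labels, X_new = small_grid_problem()
        config = tl.TrainConfig(max_epochs=60, seed=1)
        grid = tl.model_selection_grid(
            X, labels, new_datasets=[X_new],
            algorithms=("scg", "rprop"), consecutive=(6, 12),
            base_config=config, threshold=0.30)
        assert len(grid) == 4
        assert grid["accuracy_pct"].between(0, 100).all()
        assert (grid["missed_new1"] >= 0).all()
        assert grid["selected"].sum() == 1

    def test_crippled_trainer_scores_lower(self):
        # six classes on a ring: one epoch cannot sort this out
        rng = np.random.default_rng(9)
        angles = np.linspace(0, 2 * np.pi, 7)[:6]
        centers = np.column_stack([np.cos(angles), np.sin(angles)]) * 2.5
        labels = rng.integers(1, 7, 180)
        X = centers[labels - 1] + 0.4 * rng.normal(size=(180, 2))
        full = tl.model_selection_grid(
            X, labels, algorithms=("scg",), consecutive=(10,),
            base_config=tl.TrainConfig(max_epochs=150, seed=1))
        crippled = tl.model_selection_grid(
            X, labels, algorithms=("scg",), consecutive=(10,),
            base_config=tl.TrainConfig(max_epochs=1, seed=1))
        assert (crippled["accuracy_pct"].iloc[0]
                < full["accuracy_pct"].iloc[0])

    def test_selected_row_obeys_two_stage_rule(self, tmaze_fit):
        """Independent check: the flagged network has top accuracy among
        rows that are statistically tied with the best, with the missed
        count as the tie-break."""
        X, labels = tmaze_fit["X"][:300], tmaze_fit["labels"][:300]
        grid = tl.model_selection_grid(
            X, labels, new_datasets=[tmaze_fit["X"][300:400]],
            algorithms=("scg", "rprop"), consecutive=(10,),
            base_config=tl.TrainConfig(max_epochs=40, seed=3))
        winner = grid[grid["selected"]].iloc[0]
        best_acc = grid["accuracy_pct"].max()
        assert winner["accuracy_pct"] <= best_acc
        # the winner can only trail the top accuracy if it missed fewer
        if winner["accuracy_pct"] < best_acc:
            top = grid.loc[grid["accuracy_pct"].idxmax()]
            assert winner["missed_new1"] <= top["missed_new1"]


class TestEvaluateDecisions:
    def test_missed_cases_stay_in_accuracy_denominator(self):
        probs = np.array([[0.9, 0.1], [0.52, 0.48], [0.5, 0.5], [0.5, 0.5]])
        decisions = decide_batch(probs, 0.51)
        report = evaluate_decisions(decisions, [1, 1, 2, 2])
        assert report["n_missed"] == 2
        assert report["accuracy_pct"] == 50.0  # 2 correct of 4 total
        assert report["counts"].n_cases == 2  # missed excluded from counts
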