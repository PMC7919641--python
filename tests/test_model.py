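import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxpipe.balance import SmoteConfig
from pgxpipe.model import (
    FAST_GRIDS,
    ConfusionMatrix,
    UndefinedMetricError,
    auc,
    comparator_metrics,
    compute_metrics,
    confusion_at_threshold,
    evaluate_test,
    make_learner,
    predict_new,
    predict_scores,
    repeated_cv_train,
    stratified_partition,
    summarize_resamples,
    variable_importance,
)


def pair_count_auc(scores, labels):
    """Independent oracle: exhaustive positive/negative pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestStratifiedPartition:
    def test_per_class_counts(self):
        y = np.array([True] * 20 + [False] * 80)
        train, test = stratified_partition(y, 0.7, seed=0)
        assert y[train].sum() == 14
        assert abs(len(train) - 70) <= 1

    def test_partition_property(self):
        y = np.array([True] * 13 + [False] * 37)
        train, test = stratified_partition(y, 0.7, seed=1)
        assert set(train) | set(test) == set(range(50))
        assert set(train) & set(test) == set()

    def test_default_fraction_is_70_percent(self):
        import inspect

        sig = inspect.signature(stratified_partition)
        assert sig.parameters["train_fraction"].default == 0.70

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_partition(np.ones(10, dtype=bool), 0.7)

    def test_bad_fraction_rejected(self):
        y = np.array([True, False] * 5)
        for frac in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                stratified_partition(y, frac)


class TestAuc:
    def test_perfectly_separated(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]) == 1.0

    def test_three_point_pair_count(self):
        # pairs: (0.9 vs 0.8) concordant, (0.4 vs 0.8) discordant -> 0.5
        assert auc([0.9, 0.8, 0.4], [True, False, True]) == pytest.approx(0.5)

    def test_constant_scores_give_half(self):
        assert auc([0.3] * 6, [True, False] * 3) == pytest.approx(0.5)

    def test_one_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.2], [True, True])

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(5, 60),
        seed=st.integers(0, 10_000),
        ties=st.booleans(),
    )
    def test_matches_pair_counting_oracle(self, n, seed, ties):
        rng = np.random.default_rng(seed)
        scores = rng.random(n)
        if ties:
            scores = np.round(scores, 1)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert auc(scores, labels) == pytest.approx(pair_count_auc(scores, labels))

    def test_exact_equality_up_to_n200(self):
        rng = np.random.default_rng(99)
        scores = np.round(rng.random(200), 2)
        labels = rng.random(200) < 0.3
        assert auc(scores, labels) == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12
        )


class TestConfusionAndMetrics:
    def test_printed_test_counts_recover_reported_rates(self):
        # formula check on the published held-out count layout
        cm = ConfusionMatrix(tp=140, fn=63, fp=686, tn=10716)
        m = compute_metrics(cm)
        assert m.sensitivity == pytest.approx(0.6897, abs=5e-4)
        assert m.specificity == pytest.approx(0.9398, abs=5e-4)
        assert m.accuracy == pytest.approx(0.9354, abs=5e-4)

    def test_table_shape(self):
        cm = ConfusionMatrix(tp=140, fn=63, fp=686, tn=10716)
        table = cm.to_table()
        assert list(table.index) == ["neutral", "PGx"]
        assert list(table.columns) == ["not_annotated", "annotated"]
        assert table.loc["neutral", "not_annotated"] == 10716
        assert table.loc["neutral", "annotated"] == 63
        assert table.loc["PGx", "not_annotated"] == 686
        assert table.loc["PGx", "annotated"] == 140

    def test_perfect_classifier(self):
        cm = confusion_at_threshold(
            np.array([0.9, 0.8, 0.1]), np.array([True, True, False]), 0.5
        )
        assert cm.fp == 0 and cm.fn == 0

    def test_all_neutral_prediction(self):
        cm = confusion_at_threshold(
            np.array([0.1, 0.2, 0.3]), np.array([True, False, False]), 0.5
        )
        assert cm.tp == 0 and cm.tn == 2

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, tn=0, fn=0)

    def test_one_class_metrics_rejected(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))


class TestSummaries:
    def test_constant_vector(self):
        df = pd.DataFrame({"roc_auc": [0.9] * 10})
        summary = summarize_resamples(df)
        assert (summary.loc["roc_auc"] == 0.9).all()

    def test_linear_interpolation_median(self):
        # sorting oracle: median of {0.1, 0.2, 0.3, 0.4} under type-7
        df = pd.DataFrame({"m": [0.4, 0.1, 0.3, 0.2]})
        assert summarize_resamples(df).loc["m", "Median"] == pytest.approx(0.25)

    def test_six_columns_in_order(self):
        df = pd.DataFrame({"m": [0.1, 0.5]})
        assert list(summarize_resamples(df).columns) == [
            "Minimum", "1st Quartile", "Median", "Mean", "3rd Quartile", "Maximum",
        ]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_resamples(pd.DataFrame({"m": []}))


class TestRepeatedCV:
    def test_fifty_resample_rows(self, separable_data):
        X, y = separable_data
        cv, _ = repeated_cv_train(
            "gradient_boosted_trees", X, y, folds=5, repeats=10,
            seed=0, param_grid=FAST_GRIDS["gradient_boosted_trees"],
        )
        assert len(cv.resample_metrics) == 50
        assert set(cv.resample_metrics.columns) == {"roc_auc", "sensitivity", "specificity"}
        assert ((cv.resample_metrics >= 0) & (cv.resample_metrics <= 1)).all().all()

    def test_separable_data_perfect_sensitivity(self, separable_data):
        X, y = separable_data
        cv, fitted = repeated_cv_train(
            "gradient_boosted_trees", X, y, folds=5, repeats=2,
            seed=1, param_grid=FAST_GRIDS["gradient_boosted_trees"],
        )
        assert cv.summary.loc["sensitivity", "Median"] == 1.0
        cm = evaluate_test(fitted, X, y)
        assert cm.fn == 0 and cm.fp == 0

    def test_resample_assignment_is_partition(self, separable_data):
        X, y = separable_data
        folds, repeats = 5, 2
        cv, _ = repeated_cv_train(
            "random_forest", X, y, folds=folds, repeats=repeats,
            seed=2, param_grid=FAST_GRIDS["random_forest"],
        )
        for r in range(repeats):
            seen = np.concatenate(
                [cv.provenance[r * folds + f]["assessment"] for f in range(folds)]
            )
            assert sorted(seen) == list(range(len(X)))

    def test_no_assessment_sample_in_smote_sources(self, separable_data):
        X, y = separable_data
        cv, _ = repeated_cv_train(
            "logit_boost", X, y, folds=5, repeats=2,
            seed=3, param_grid=FAST_GRIDS["logit_boost"],
        )
        for record in cv.provenance:
            assert not set(record["assessment"]) & set(record["smote_sources"])

    def test_hyperparameter_selection_maximizes_mean_metric(self, separable_data):
        X, y = separable_data
        grid = {"n_estimators": [5, 50], "max_depth": [2], "learning_rate": [0.3]}
        cv, _ = repeated_cv_train(
            "gradient_boosted_trees", X, y, folds=3, repeats=1,
            selection_metric="roc_auc", seed=4, param_grid=grid,
        )
        assert cv.chosen_hyperparameters["n_estimators"] in (5, 50)

    def test_minority_smaller_than_folds_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 3)))
        y = np.zeros(30, dtype=bool)
        y[:3] = True
        with pytest.raises(ValueError, match="stratify"):
            repeated_cv_train("random_forest", X, y, folds=5, repeats=1)

    def test_unknown_learner_and_metric_rejected(self, separable_data):
        X, y = separable_data
        with pytest.raises(ValueError):
            repeated_cv_train("svm", X, y)
        with pytest.raises(ValueError):
            repeated_cv_train("random_forest", X, y, selection_metric="f1")

    def test_deterministic_given_seed(self, separable_data):
        X, y = separable_data
        a, _ = repeated_cv_train(
            "gradient_boosted_trees", X, y, folds=3, repeats=1,
            seed=5, param_grid=FAST_GRIDS["gradient_boosted_trees"],
        )
        b, _ = repeated_cv_train(
            "gradient_boosted_trees", X, y, folds=3, repeats=1,
            seed=5, param_grid=FAST_GRIDS["gradient_boosted_trees"],
        )
        pd.testing.assert_frame_equal(a.resample_metrics, b.resample_metrics)


class TestImportanceAndPrediction:
    def test_single_informative_predictor_scores_100(self, separable_data):
        X, y = separable_data
        model = make_learner("gradient_boosted_trees", {"n_estimators": 30}, seed=0)
        model.fit(X, y)
        imp = variable_importance(model, list(X.columns))
        assert imp.table.iloc[0]["importance"] == pytest.approx(100.0)
        assert imp.top_variable() == "f0"

    def test_top_entry_always_exactly_100(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        y = X[:, 1] + 0.3 * rng.normal(size=200) > 0
        model = make_learner("random_forest", {"n_estimators": 20}, seed=1)
        model.fit(X, y)
        imp = variable_importance(model)
        assert imp.table["importance"].iloc[0] == pytest.approx(100.0)
        assert imp.table["importance"].is_monotonic_decreasing

    def test_predict_new_excludes_annotated(self, separable_data):
        X, y = separable_data
        model = make_learner("gradient_boosted_trees", {}, seed=0)
        model.fit(X.to_numpy(), y)
        ids = [f"v{i}" for i in range(len(X))]
        annotated = {f"v{i}" for i in np.flatnonzero(y)}
        new = predict_new(model, X, annotated, threshold=0.5, ids=ids)
        assert not new & annotated

    def test_threshold_one_with_sub_unit_scores_is_empty(self):
        class Stub:
            classes_ = np.array([False, True])

            def predict_proba(self, X):
                n = len(X)
                return np.column_stack([np.full(n, 0.5), np.full(n, 0.5)])

        out = predict_new(Stub(), np.zeros((4, 2)), set(), threshold=1.0)
        assert out == set()

    def test_predict_scores_two_columns(self, separable_data):
        X, y = separable_data
        model = make_learner("random_forest", {"n_estimators": 10}, seed=2)
        model.fit(X.to_numpy(), y)
        frame = predict_scores(model, X)
        assert list(frame.columns) == ["variant_id", "probability"]
        assert len(frame) == len(X)


class TestComparators:
    def test_score_equal_to_label_is_perfect(self):
        labels = np.array([True, False, True, False])
        table = pd.DataFrame({"m": labels.astype(float)})
        metrics, log = comparator_metrics(table, labels, {"m": (0.5, "higher")})
        m = metrics[0]
        assert m.sensitivity == m.specificity == m.accuracy == m.auc == 1.0
        assert log.empty

    def test_constant_score_auc_half(self):
        labels = np.array([True, False, True, False])
        table = pd.DataFrame({"m": [0.2] * 4})
        metrics, _ = comparator_metrics(table, labels, {"m": (0.5, "higher")})
        assert metrics[0].auc == pytest.approx(0.5)

    def test_lower_direction_flips_orientation(self):
        labels = np.array([True, True, False, False])
        table = pd.DataFrame({"sift": [0.01, 0.02, 0.8, 0.9]})
        metrics, _ = comparator_metrics(table, labels, {"sift": (0.05, "lower")})
        assert metrics[0].sensitivity == 1.0
        assert metrics[0].auc == 1.0

    def test_missing_scores_excluded_and_logged(self):
        labels = np.array([True, False, True, False])
        table = pd.DataFrame({"m": [0.9, 0.1, np.nan, 0.2]})
        metrics, log = comparator_metrics(table, labels, {"m": (0.5, "higher")})
        assert log.loc[0, "excluded_rows"] == 1
        assert metrics[0].sensitivity == 1.0

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            comparator_metrics(
                pd.DataFrame({"m": [0.1]}), np.array([True, False]), {"m": (0.5, "higher")}
            )
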