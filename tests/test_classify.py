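"""Classifiers, evaluation protocols, gain explainability."""

import json

import numpy as np
import pandas as pd
import pytest

from ifcprofiler.classify import (
    ModelSpec,
    channel_ablation,
    f1_macro,
    fit,
    gain_importance,
    importance_protocol,
    learning_curve,
    leave_one_donor_out_cv,
    predict,
    predict_proba,
    predict_with_entropy,
    repeated_stratified_cv,
)
from ifcprofiler.selection import SelectionConfig


def toy_separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["neg", "pos"])[rng.integers(0, 2, n)]
    X = pd.DataFrame(
        {
            "a": rng.normal(0, 1, n) + 10 * (y == "pos"),
            "b": rng.normal(0, 1, n),
        }
    )
    return X, y


def brute_force_f1_macro(y_true, y_pred):
    labels = sorted(set(y_true) | set(y_pred))
    f1s = []
    for c in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return sum(f1s) / len(f1s)


def tree_walk_average_gain(model):
    """Independent oracle: re-enumerate splits from the booster JSON dump."""
    booster = model.estimator.get_booster()
    totals, counts = {}, {}

    def walk(node):
        if "split" in node:
            f = node["split"]
            totals[f] = totals.get(f, 0.0) + node["gain"]
            counts[f] = counts.get(f, 0) + 1
            for child in node.get("children", []):
                walk(child)

    for dump in booster.get_dump(dump_format="json", with_stats=True):
        walk(json.loads(dump))
    avg = pd.Series(0.0, index=list(model.feature_names))
    for f in totals:
        avg[f] = totals[f] / counts[f]
    total = avg.sum()
    return avg / total if total > 0 else avg


class TestFitPredict:
    @pytest.mark.parametrize(
        "kind",
        ["logistic-regression", "linear-discriminant", "linear-SVM",
         "random-forest", "gradient-boosting"],
    )
    def test_separable_toy_perfect_training_f1(self, kind):
        X, y = toy_separable()
        model = fit(ModelSpec(kind=kind, seed=0), X, y)
        assert f1_macro(y, predict(model, X)) == 1.0

    @pytest.mark.parametrize("kind", ["gradient-boosting", "random-forest"])
    def test_proba_rows_sum_to_one(self, kind):
        X, y = toy_separable()
        model = fit(ModelSpec(kind=kind, seed=0), X, y)
        probs = predict_proba(model, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_column_permutation_invariance_for_tree_model(self):
        X, y = toy_separable()
        model = fit(ModelSpec(seed=0), X, y)
        permuted = X[["b", "a"]]
        np.testing.assert_array_equal(predict(model, X), predict(model, permuted))

    def test_single_class_rejected(self):
        X, _ = toy_separable()
        with pytest.raises(ValueError):
            fit(ModelSpec(), X, np.repeat("only", len(X)))

    def test_missing_values_rejected(self):
        X, y = toy_separable()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit(ModelSpec(), X, y)


class TestF1Macro:
    def test_perfect_prediction(self):
        assert f1_macro(list("abcabc"), list("abcabc")) == 1.0

    def test_hand_computed_example(self):
        assert f1_macro(list("aabb"), list("abbb")) == pytest.approx(0.73333333)

    def test_constant_predictor_balanced_two_class(self):
        assert f1_macro(list("aabb"), list("aaaa")) == pytest.approx(1 / 3)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 30))
            k = int(rng.integers(2, 5))
            y_true = rng.integers(0, k, n).astype(str)
            y_pred = rng.integers(0, k, n).astype(str)
            assert f1_macro(y_true, y_pred) == pytest.approx(
                brute_force_f1_macro(y_true, y_pred)
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            f1_macro([], [])


class TestCrossValidation:
    def test_fold_count_and_determinism(self):
        X, y = toy_separable(n=80)
        r1 = repeated_stratified_cv(X, y, ModelSpec(seed=0), folds=4, repeats=2, seed=3)
        r2 = repeated_stratified_cv(X, y, ModelSpec(seed=0), folds=4, repeats=2, seed=3)
        assert len(r1.fold_scores) == 8
        assert r1.fold_scores == r2.fold_scores

    def test_confusion_row_sums_are_class_counts(self):
        X, y = toy_separable(n=80)
        res = repeated_stratified_cv(X, y, ModelSpec(seed=0), folds=4, repeats=2, seed=0)
        counts = pd.Series(y).value_counts()
        for c in res.confusion.index:
            assert res.confusion.loc[c].sum() == counts[c]

    def test_label_permutation_near_chance(self, small_cohort_features):
        table, labels, _ = small_cohort_features
        rng = np.random.default_rng(0)
        permuted = rng.permutation(labels.to_numpy())
        res = repeated_stratified_cv(
            table.df, permuted, ModelSpec(seed=0), folds=3, repeats=1, seed=0
        )
        assert res.mean < 0.25  # chance level for 9 classes is ~1/9

    def test_cohort_classes_separable(self, small_cohort_features):
        table, labels, _ = small_cohort_features
        res = repeated_stratified_cv(
            table.df, labels.to_numpy(), ModelSpec(seed=0), folds=3, repeats=1, seed=0
        )
        assert res.mean > 0.9


class TestLeaveOneDonorOut:
    def test_one_fold_per_donor(self, small_cohort_features, small_cohort):
        table, labels, _ = small_cohort_features
        donors = small_cohort.index.table.set_index("record_id").loc[
            table.df.index, "donor_id"
        ]
        res = leave_one_donor_out_cv(
            table.df, labels.to_numpy(), donors.to_numpy(), ModelSpec(seed=0)
        )
        assert len(res.fold_scores) == donors.nunique()
        assert set(res.per_fold_labels) == set(donors.unique())
        assert res.mean > 0.85

    def test_two_donor_minimum(self):
        X, y = toy_separable()
        with pytest.raises(ValueError):
            leave_one_donor_out_cv(X, y, np.repeat("d1", len(X)), ModelSpec())


class TestGainImportance:
    def test_single_feature_model_scores_one(self):
        X, y = toy_separable()
        model = fit(ModelSpec(seed=0), X[["a"]], y)
        gains = gain_importance(model)
        assert gains["a"] == pytest.approx(1.0)

    def test_scores_sum_to_one_and_noise_near_zero(self, rng):
        X, y = toy_separable(n=400)
        X["pure_noise"] = rng.normal(0, 1, len(X))
        model = fit(ModelSpec(seed=0), X, y)
        gains = gain_importance(model)
        assert gains.sum() == pytest.approx(1.0)
        assert gains["pure_noise"] < 0.05
        assert gains["a"] > 0.8

    def test_matches_tree_walk_oracle(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            n = 120
            y = r.integers(0, 3, n).astype(str)
            X = pd.DataFrame(
                r.normal(0, 1, (n, 6)), columns=[f"f{i}" for i in range(6)]
            )
            X["f0"] += (y == "0") * 1.5
            model = fit(ModelSpec(n_trees=3, seed=seed), X, y)
            gains = gain_importance(model)
            oracle = tree_walk_average_gain(model)
            pd.testing.assert_series_equal(gains, oracle, rtol=1e-5)

    def test_non_tree_model_unsupported(self):
        X, y = toy_separable()
        model = fit(ModelSpec(kind="logistic-regression"), X, y)
        with pytest.raises(TypeError):
            gain_importance(model)


class TestEntropy:
    def test_one_hot_zero_uniform_ln9(self):
        X, y = toy_separable()
        model = fit(ModelSpec(seed=0), X, y)
        _, probs, ent = predict_with_entropy(model, X)
        assert np.all(ent >= 0)
        assert np.all(ent <= np.log(len(model.classes)) + 1e-12)
        from scipy.stats import entropy as se

        assert se(np.eye(9)[0]) == pytest.approx(0.0)
        assert se(np.full(9, 1 / 9)) == pytest.approx(np.log(9))


class TestImportanceProtocol:
    def test_planted_features_ranked_top(self):
        rng = np.random.default_rng(0)
        n = 300
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(
            rng.normal(0, 1, (n, 40)), columns=[f"n{i:02d}" for i in range(40)]
        )
        for j, name in enumerate(["s1", "s2", "s3"]):
            X[name] = rng.normal(0, 1, n) + (2 * y - 1) * (1.5 + 0.3 * j)
        ranking = importance_protocol(
            X, y, SelectionConfig(top_k=10, n_clusters=10, seed=0),
            n_repeats=2, k_range=(10, 20), folds=3, seed=0,
        )
        assert {"s1", "s2", "s3"} <= set(ranking.index[:10])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 120)
        X = pd.DataFrame(rng.normal(0, 1, (120, 12)),
                         columns=[f"f{i}" for i in range(12)])
        X["sig"] = (2 * y - 1) + rng.normal(0, 0.5, 120)
        a = importance_protocol(X, y, n_repeats=1, k_range=(5, 8), folds=3, seed=5)
        b = importance_protocol(X, y, n_repeats=1, k_range=(5, 8), folds=3, seed=5)
        pd.testing.assert_series_equal(a, b)


class TestChannelAblation:
    def test_subset_map_and_full_panel_competitive(self, small_cohort):
        records = small_cohort.records
        labels = small_cohort.index.labels.loc[
            [r.record_id for r in records]
        ].to_numpy()
        results = channel_ablation(
            records, labels, ("F-actin", "MHCII", "CD3", "P-CD3z"),
            ModelSpec(seed=0), folds=3, repeats=1, seed=0,
        )
        assert len(results) == 15  # all non-empty subsets of 4 fluorochromes
        full = results[("F-actin", "MHCII", "CD3", "P-CD3z")].mean
        best_single = max(results[(ch,)].mean for ch in ("F-actin", "MHCII", "CD3", "P-CD3z"))
        assert full >= best_single - 0.05


class TestLearningCurve:
    def test_full_fraction_equals_full_data_fit(self, small_cohort_features):
        table, labels, _ = small_cohort_features
        from ifcprofiler.core_data import stratified_split
        from .test_core_data import index_from_labels

        idx = index_from_labels(labels.to_numpy())
        mapping = dict(zip(idx.record_ids, table.df.index))
        tr, te = stratified_split(idx, train_fraction=0.7, seed=0)
        tr_ids = [mapping[r] for r in tr.record_ids]
        te_ids = [mapping[r] for r in te.record_ids]
        curve = learning_curve(
            table.df.loc[tr_ids], labels.loc[tr_ids].to_numpy(),
            table.df.loc[te_ids], labels.loc[te_ids].to_numpy(),
            ModelSpec(seed=0), fractions=(0.3, 1.0), n_repeats=2, seed=0,
        )
        assert list(curve["fraction"]) == [0.3, 1.0]
        assert curve["mean_f1"].iloc[1] >= curve["mean_f1"].iloc[0] - 0.05

    def test_deterministic(self, small_cohort_features):
        table, labels, _ = small_cohort_features
        half = len(table.df) // 2
        args = (
            table.df.iloc[:half], labels.iloc[:half].to_numpy(),
            table.df.iloc[half:], labels.iloc[half:].to_numpy(),
        )
        c1 = learning_curve(*args, ModelSpec(seed=0), fractions=(0.5,), n_repeats=2, seed=1)
        c2 = learning_curve(*args, ModelSpec(seed=0), fractions=(0.5,), n_repeats=2, seed=1)
        pd.testing.assert_frame_equal(c1, c2)
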