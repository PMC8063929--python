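"""Classifiers, metrics, balanced resampling and nested CV integrity."""

import numpy as np
import pandas as pd
import pytest

from erpemd.evaluate import (
    CVConfig,
    ConfusionCounts,
    balanced_resample,
    compute_metrics,
    knn_classify,
    nested_cv,
    risk_labels,
    run_experiment,
    svm_classify,
)


class TestKnn:
    def test_exact_match_wins_with_k1(self):
        Xtr = np.array([[0.0, 0], [5, 5], [9, 9]])
        ytr = np.array(["a", "b", "a"])
        assert knn_classify(Xtr, ytr, np.array([[5.0, 5]]), k=1)[0] == "b"

    def test_unanimous_training_labels(self, rng):
        Xtr = rng.standard_normal((10, 3))
        ytr = np.array(["z"] * 10)
        preds = knn_classify(Xtr, ytr, rng.standard_normal((4, 3)), k=3)
        assert np.all(preds == "z")

    def test_matches_exhaustive_distance_oracle(self, rng):
        for k in [1, 3, 5, 7]:
            Xtr = rng.standard_normal((20, 4))
            ytr = rng.choice(["a", "b"], 20)
            Xte = rng.standard_normal((10, 4))
            preds = knn_classify(Xtr, ytr, Xte, k)
            for i in range(10):
                d = np.sqrt(((Xtr - Xte[i]) ** 2).sum(axis=1))
                nearest = np.argsort(d, kind="stable")[:k]
                votes = {}
                for j in nearest:
                    votes[ytr[j]] = votes.get(ytr[j], 0) + 1
                top = max(votes.values())
                tied = {c for c, v in votes.items() if v == top}
                if len(tied) == 1:
                    expected = tied.pop()
                else:
                    expected = next(ytr[j] for j in nearest if ytr[j] in tied)
                assert preds[i] == expected

    def test_agrees_with_sklearn_for_odd_k_binary(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        Xtr = rng.standard_normal((30, 5))
        ytr = rng.choice(["a", "b"], 30)
        Xte = rng.standard_normal((15, 5))
        for k in [1, 3, 5]:
            ours = knn_classify(Xtr, ytr, Xte, k)
            sk = KNeighborsClassifier(n_neighbors=k).fit(Xtr, ytr).predict(Xte)
            np.testing.assert_array_equal(ours, sk)

    def test_tie_goes_to_nearest_tied_class_member(self):
        # k=2 with one vote each: the class of the single nearest wins
        Xtr = np.array([[0.0], [1.0]])
        ytr = np.array(["near", "far"])
        assert knn_classify(Xtr, ytr, np.array([[0.1]]), k=2)[0] == "near"

    def test_invalid_k_rejected(self):
        X = np.ones((3, 2))
        y = np.array(["a", "b", "a"])
        with pytest.raises(ValueError):
            knn_classify(X, y, X, k=0)
        with pytest.raises(ValueError):
            knn_classify(X, y, X, k=4)


class TestSvm:
    def test_separable_data_fit_perfectly_with_linear_kernel(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        preds = svm_classify(X, y, X, kernel="linear", C=1.0)
        assert np.mean(preds == y) == 1.0

    def test_label_flip_swaps_predictions(self, rng):
        X = np.vstack([rng.normal(-2, 0.5, (15, 2)), rng.normal(2, 0.5, (15, 2))])
        y = np.array(["a"] * 15 + ["b"] * 15)
        flip = {"a": "b", "b": "a"}
        y2 = np.array([flip[v] for v in y])
        Xte = rng.standard_normal((10, 2))
        p1 = svm_classify(X, y, Xte, "linear", 1.0)
        p2 = svm_classify(X, y2, Xte, "linear", 1.0)
        np.testing.assert_array_equal(p1, np.array([flip[v] for v in p2]))

    def test_xor_linear_fails_gaussian_succeeds(self):
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array(["a", "a", "b", "b"])
        lin = svm_classify(X, y, X, "linear", 100.0)
        assert np.mean(lin == y) < 1.0
        rbf = svm_classify(X, y, X, "gaussian_fine", 100.0)
        assert np.mean(rbf == y) == 1.0

    def test_single_class_training_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="two classes"):
            svm_classify(X, np.array(["a"] * 4), X)

    def test_unknown_kernel_rejected(self, rng):
        X = rng.standard_normal((6, 2))
        y = np.array(["a", "b"] * 3)
        with pytest.raises(ValueError, match="kernel"):
            svm_classify(X, y, X, kernel="sigmoid")


class TestMetrics:
    def test_perfect_classifier(self):
        c = ConfusionCounts(tp=1, tn=1, fp=0, fn=0, positive_class="p")
        assert compute_metrics(c) == (1.0, 1.0, 1.0)

    def test_direct_ratio_computation(self):
        c = ConfusionCounts(tp=3, tn=2, fp=1, fn=2, positive_class="p")
        acc, sens, spec = compute_metrics(c)
        assert acc == pytest.approx(0.625)
        assert sens == pytest.approx(0.6)
        assert spec == pytest.approx(2.0 / 3.0)

    def test_all_positive_predictions_give_zero_specificity(self):
        c = ConfusionCounts(tp=5, tn=0, fp=3, fn=0, positive_class="p")
        assert compute_metrics(c)[2] == 0.0

    def test_undefined_metric_flagged_as_nan(self):
        c = ConfusionCounts(tp=0, tn=4, fp=0, fn=0, positive_class="p")
        acc, sens, spec = compute_metrics(c)
        assert np.isnan(sens) and spec == 1.0 and acc == 1.0

    def test_metric_identities(self):
        c = ConfusionCounts(tp=7, tn=5, fp=2, fn=3, positive_class="p")
        acc, sens, spec = compute_metrics(c)
        assert acc * c.total == pytest.approx(c.tp + c.tn)
        assert sens * (c.tp + c.fn) == pytest.approx(c.tp)


class TestBalancedResample:
    def test_each_repeat_has_size_34(self):
        minority = [f"asd{i}" for i in range(17)]
        majority = [f"no{i}" for i in range(33)]
        sets = balanced_resample(minority, majority, repeats=5, seed=0)
        assert len(sets) == 5
        for s in sets:
            assert len(s) == 34
            assert set(minority) <= set(s)
            drawn = set(s) - set(minority)
            assert len(drawn) == 17 and drawn <= set(majority)

    def test_equal_sizes_return_full_set(self):
        minority = ["a", "b"]
        majority = ["c", "d"]
        sets = balanced_resample(minority, majority, repeats=2, seed=1)
        for s in sets:
            assert sorted(s) == ["a", "b", "c", "d"]

    def test_deterministic_and_varying_across_repeats(self):
        minority = list(range(5))
        majority = list(range(100, 130))
        a = balanced_resample(minority, majority, repeats=5, seed=3)
        b = balanced_resample(minority, majority, repeats=5, seed=3)
        assert a == b
        assert len({tuple(s) for s in a}) > 1

    def test_minority_larger_rejected(self):
        with pytest.raises(ValueError, match="minority"):
            balanced_resample([1, 2, 3], [4], repeats=1, seed=0)


def _synthetic_table(n_ctrl=44, n_hr=50, n_cols=20, seed=0, oracle=False):
    rng = np.random.default_rng(seed)
    groups = ["control"] * n_ctrl + ["HR-noASD"] * (n_hr - 17) + ["HR-ASD"] * 17
    X = rng.standard_normal((len(groups), n_cols))
    y = risk_labels(groups)
    if oracle:
        X[:, 0] = (y == "HR").astype(float)
    table = pd.DataFrame(
        X,
        index=[f"s{i}" for i in range(len(groups))],
        columns=[f"f{j}" for j in range(n_cols)],
    )
    return table, groups, y


class TestNestedCV:
    def test_outer_folds_partition_94_subjects(self):
        table, groups, y = _synthetic_table()
        cfg = CVConfig(outer_folds=10, inner_folds=9, selection_k=5, seed=0)
        report = nested_cv(table, y, "knn", cfg, positive_class="HR")
        sizes = sorted(len(f.test_index) for f in report.folds)
        assert sizes == [9] * 6 + [10] * 4  # 94 = 4*10 + 6*9
        all_idx = np.concatenate([f.test_index for f in report.folds])
        assert sorted(all_idx.tolist()) == list(range(94))

    def test_stratification_keeps_class_ratio_within_one(self):
        table, groups, y = _synthetic_table()
        cfg = CVConfig(outer_folds=10, inner_folds=9, selection_k=5, seed=0)
        report = nested_cv(table, y, "knn", cfg, positive_class="HR")
        global_pos = np.mean(y == "HR")
        for f in report.folds:
            n_pos = int(np.sum(f.truth == "HR"))
            expected = global_pos * len(f.truth)
            assert abs(n_pos - expected) <= 1.0

    def test_oracle_feature_yields_perfect_outer_accuracy(self):
        table, groups, y = _synthetic_table(oracle=True)
        cfg = CVConfig(outer_folds=10, inner_folds=9, selection_k=3, seed=0)
        for clf in ["knn", "svm"]:
            report = nested_cv(table, y, clf, cfg, positive_class="HR")
            assert report.accuracy == 1.0

    def test_no_leakage_from_outer_test_rows(self):
        """Mutating an outer-test subject's features changes neither the
        selected features nor the hyperparameters of that fold."""
        table, groups, y = _synthetic_table(seed=4)
        cfg = CVConfig(outer_folds=5, inner_folds=4, selection_k=5, seed=2)
        base = nested_cv(table, y, "knn", cfg, positive_class="HR")
        fold = base.folds[2]
        mutated = table.copy()
        mutated.iloc[fold.test_index] = 1e3  # wreck the test rows
        again = nested_cv(mutated, y, "knn", cfg, positive_class="HR")
        assert again.folds[2].hyperparams == fold.hyperparams
        assert again.folds[2].selected_columns == fold.selected_columns

    def test_metrics_match_pooled_confusion(self):
        table, groups, y = _synthetic_table(seed=9)
        cfg = CVConfig(outer_folds=5, inner_folds=4, selection_k=5, seed=0)
        report = nested_cv(table, y, "knn", cfg, positive_class="HR")
        acc, sens, spec = compute_metrics(report.confusion)
        assert report.accuracy == acc
        assert report.confusion.total == 94

    def test_mismatched_rows_rejected(self):
        table, groups, y = _synthetic_table()
        with pytest.raises(ValueError, match="sample count"):
            nested_cv(table, y[:-1], "knn", CVConfig(), positive_class="HR")


class TestRunExperiment:
    def test_risk_uses_hr_as_positive_class(self):
        table, groups, _ = _synthetic_table(oracle=True)
        res = run_experiment(
            table, groups, "risk", "knn",
            CVConfig(outer_folds=5, inner_folds=4, selection_k=1, seed=0),
        )
        assert res.reports[0].confusion.positive_class == "HR"
        assert res.summary["accuracy"] == 1.0

    def test_outcome_runs_five_balanced_resamples_of_34(self):
        table, groups, _ = _synthetic_table()
        res = run_experiment(
            table, groups, "outcome", "knn",
            CVConfig(outer_folds=5, inner_folds=4, selection_k=3, seed=0),
        )
        assert len(res.reports) == 5
        for rep in res.reports:
            assert rep.confusion.total == 34
            assert rep.confusion.positive_class == "HR-ASD"
        assert res.summary["n_reports"] == 5

    def test_unknown_problem_rejected(self):
        table, groups, _ = _synthetic_table()
        with pytest.raises(ValueError, match="problem"):
            run_experiment(table, groups, "triage", "knn")

    def test_condition_and_imf_ablations_use_18_and_36_columns(self, rng):
        from erpemd.features import column_label, feature_columns

        cols = [column_label(c) for c in feature_columns()]
        groups = ["control"] * 12 + ["HR-noASD"] * 8 + ["HR-ASD"] * 4
        X = rng.standard_normal((24, 108))
        table = pd.DataFrame(
            X, index=[f"s{i}" for i in range(24)], columns=cols
        )
        cfg = CVConfig(outer_folds=3, inner_folds=2, selection_k=5, seed=0)
        res_cond = run_experiment(table, groups, "risk", "knn", cfg, variant="direct_gaze")
        res_imf = run_experiment(table, groups, "risk", "knn", cfg, variant="imf2")
        # every selected feature comes from the restricted column set
        for f in res_cond.reports[0].folds:
            assert all(str(c).startswith("direct_gaze|") for c in f.selected_columns)
        for f in res_imf.reports[0].folds:
            assert all("|imf2|" in str(c) for c in f.selected_columns)


def test_cv_config_validation():
    with pytest.raises(ValueError):
        CVConfig(outer_folds=1)
    with pytest.raises(ValueError):
        CVConfig(knn_grid=())
    with pytest.raises(ValueError):
        CVConfig(selection_k=0)
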