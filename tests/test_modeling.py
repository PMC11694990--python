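"""Replica-aware cross-validation, metrics, classifier determinism."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from ctgcompress import (
    ClassifierSpec,
    custom_folds,
    evaluate_feature_set,
    fit_predict,
    metrics,
    stratified_folds,
)


def make_table(n_orig=7, n_rep=6, n_maj=54, n_feat=4, seed=0):
    rng = np.random.default_rng(seed)
    rows, index = [], []
    for i in range(n_orig):
        index.append(f"a{i}")
        rows.append(("acidemic", "original"))
        for j in range(n_rep):
            index.append(f"a{i}_r{j}")
            rows.append(("acidemic", f"replica:a{i}"))
    for i in range(n_maj):
        index.append(f"n{i}")
        rows.append(("nonacidemic", "original"))
    t = pd.DataFrame(rng.normal(size=(len(index), n_feat)),
                     columns=[f"f{k}" for k in range(n_feat)], index=index)
    t["group"] = [r[0] for r in rows]
    t["origin"] = [r[1] for r in rows]
    return t


class TestCustomFolds:
    def test_103_rows_gives_7_folds_of_89_train_14_test(self):
        table = make_table()
        assert len(table) == 103
        folds = custom_folds(table, rng=np.random.default_rng(0))
        assert len(folds) == 7
        for train, test in folds:
            assert len(train) == 89
            assert len(test) == 14
            groups = table.loc[test, "group"]
            assert (groups == "acidemic").sum() == 7
            assert (groups == "nonacidemic").sum() == 7

    def test_each_fold_partitions_all_rows(self):
        table = make_table()
        for train, test in custom_folds(table, rng=np.random.default_rng(1)):
            assert set(train) | set(test) == set(table.index)
            assert set(train) & set(test) == set()

    def test_no_heldout_replica_leaks_into_training(self):
        table = make_table()
        for train, test in custom_folds(table, rng=np.random.default_rng(2)):
            held = [ix for ix in test
                    if table.loc[ix, "origin"] == "original"
                    and table.loc[ix, "group"] == "acidemic"]
            assert len(held) == 1
            assert not any(table.loc[ix, "origin"] == f"replica:{held[0]}"
                           for ix in train)

    def test_majority_test_rows_disjoint_across_folds(self):
        table = make_table()
        seen = []
        for _, test in custom_folds(table, rng=np.random.default_rng(3)):
            seen.extend(ix for ix in test if table.loc[ix, "group"] == "nonacidemic")
        assert len(seen) == len(set(seen)) == 49  # 7 folds x 7, all distinct

    def test_missing_provenance_errors(self):
        table = make_table().drop(columns=["origin"])
        with pytest.raises(ValueError):
            custom_folds(table)


class TestStratifiedFolds:
    def test_every_row_tested_once_and_minority_present(self):
        table = make_table()
        folds = stratified_folds(table, n_splits=20, rng=3)
        tested = [ix for _, test in folds for ix in test]
        assert sorted(tested) == sorted(table.index)
        for _, test in folds:
            assert (table.loc[test, "group"] == "acidemic").sum() >= 2

    def test_split_count_errors(self):
        table = make_table()
        with pytest.raises(ValueError):
            stratified_folds(table, n_splits=1)
        with pytest.raises(ValueError):
            stratified_folds(table, n_splits=50)


class TestMetrics:
    def test_hand_computed_confusion(self):
        # TP=2, FP=1, TN=3, FN=0
        y_true = [1, 1, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.1]
        m = metrics(y_true, y_pred, scores)
        assert m.recall == 1.0
        assert m.precision == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(5 / 6)
        assert m.specificity == pytest.approx(3 / 4)

    def test_perfect_and_degenerate_auc(self):
        y = [0, 1, 0, 1]
        m = metrics(y, y, [0.0, 1.0, 0.0, 1.0])
        assert all(v == 1.0 for v in m.as_dict().values())
        m2 = metrics(y, y, [0.5, 0.5, 0.5, 0.5])
        assert m2.auc == pytest.approx(0.5)

    def test_fuzz_against_brute_force_confusion(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            y_true = rng.integers(0, 2, n)
            if len(np.unique(y_true)) < 2:
                continue
            y_pred = rng.integers(0, 2, n)
            scores = rng.random(n)
            m = metrics(y_true, y_pred, scores)
            tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
            tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
            fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
            fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
            assert m.accuracy == pytest.approx((tp + tn) / n)
            assert m.recall == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            assert m.specificity == pytest.approx(tn / (tn + fp) if tn + fp else 0.0)
            assert m.auc == pytest.approx(roc_auc_score(y_true, scores))

    def test_unknown_labels_error(self):
        with pytest.raises(ValueError):
            metrics([0, 2], [0, 1], [0.1, 0.9])
        with pytest.raises(ValueError):
            metrics([], [], [])


class TestFitPredict:
    def toy(self, n=30, sep=4.0, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))])
        t = pd.DataFrame(X, columns=["f0", "f1"],
                         index=[f"r{i}" for i in range(2 * n)])
        t["group"] = ["nonacidemic"] * n + ["acidemic"] * n
        t["origin"] = "original"
        return t.sample(frac=1.0, random_state=seed)

    def test_separable_data_perfect_labels(self):
        t = self.toy()
        train, test = t.iloc[:40], t.iloc[40:]
        spec = ClassifierSpec(seed=0)
        labels, scores = fit_predict(spec, train, test)
        y = (test["group"] == "acidemic").to_numpy(int)
        assert np.array_equal(labels, y)
        assert roc_auc_score(y, scores) == 1.0

    def test_deterministic_under_seed(self):
        t = self.toy(sep=1.0)
        train, test = t.iloc[:40], t.iloc[40:]
        l1, s1 = fit_predict(ClassifierSpec(seed=5), train, test)
        l2, s2 = fit_predict(ClassifierSpec(seed=5), train, test)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(s1, s2)

    def test_permuted_labels_near_chance(self):
        aucs = []
        for s in range(10):
            rng = np.random.default_rng(s)
            t = self.toy(n=40, sep=3.0, seed=s)
            t["group"] = rng.permutation(t["group"].to_numpy())
            train, test = t.iloc[:56], t.iloc[56:]
            if train["group"].nunique() < 2 or test["group"].nunique() < 2:
                continue
            _, scores = fit_predict(ClassifierSpec(seed=s), train, test)
            aucs.append(roc_auc_score(
                (test["group"] == "acidemic").to_numpy(int), scores))
        assert 0.3 <= np.mean(aucs) <= 0.7

    def test_single_class_training_errors(self):
        t = self.toy()
        train = t[t["group"] == "acidemic"]
        with pytest.raises(ValueError):
            fit_predict(ClassifierSpec(seed=0), train, t.iloc[:5])

    def test_tree_classifiers_run(self):
        t = self.toy(n=20)
        train, test = t.iloc[:28], t.iloc[28:]
        for kind in ("random_forest", "gradient_boosted_trees"):
            spec = ClassifierSpec(
                kind=kind, seed=0,
                grid={"clf__n_estimators": [30]},
            )
            labels, scores = fit_predict(spec, train, test)
            assert len(labels) == len(test)


def test_pooled_and_averaged_aggregation_differ():
    """Pooling predictions then computing metrics is the contract; per-fold
    averaging is a different number on heterogeneous folds."""
    table = make_table(n_feat=3, seed=11)
    # inject signal so folds are heterogeneous but classifiable
    bump = (table["group"] == "acidemic").to_numpy(float)
    table["f0"] = table["f0"].to_numpy() + 1.5 * bump
    folds = custom_folds(table, rng=np.random.default_rng(4))
    spec = ClassifierSpec(seed=0, grid={"clf__C": [1.0], "clf__gamma": ["scale"]})
    pooled, _ = evaluate_feature_set(table, spec, folds, aggregate="pooled")
    averaged, _ = evaluate_feature_set(table, spec, folds, aggregate="averaged")
    assert pooled.as_dict() != averaged.as_dict()
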