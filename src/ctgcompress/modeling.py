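"""Classifier training and replica-aware evaluation.

Two validation schemes are provided.  The default, replica-aware scheme
builds one fold per original minority case: the test set is that original
plus every synthetic replica seeded from it, together with seven randomly
chosen majority cases (sampled without replacement, disjointly across folds
when possible); everything else trains the model.  The model therefore never
sees the held-out original nor any of its replicas — with 7 originals, 42
replicas and 54 majority cases this gives 7 folds of 89 training and 14 test
cases.  A stratified k-fold alternative (default 20 splits) is also exposed.

Within each fold the collinearity filter is fitted on the training rows only
and frozen, hyperparameters are chosen by grid search with inner stratified
CV on the training rows, and test predictions are pooled across folds before
the six performance metrics (accuracy, recall/sensitivity, specificity,
precision, F1, AUC) are computed once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import META_COLUMNS, collinearity_filter, select_feature_set

POSITIVE = "acidemic"
NEGATIVE = "nonacidemic"

DEFAULT_SVM_GRID = {
    "clf__C": [0.1, 1.0, 10.0, 100.0],
    "clf__gamma": ["scale", 0.01, 0.1, 1.0],
}
DEFAULT_RF_GRID = {
    "clf__n_estimators": [100, 300],
    "clf__max_depth": [None, 3, 6],
}
DEFAULT_GBT_GRID = {
    "clf__n_estimators": [100, 300],
    "clf__max_depth": [2, 4],
    "clf__learning_rate": [0.1, 0.3],
}


@dataclass
class ClassifierSpec:
    """Classifier kind plus hyperparameter grid for the inner search."""

    kind: str = "svm_rbf"  # svm_rbf | random_forest | gradient_boosted_trees
    grid: dict = field(default_factory=dict)
    class_weighting: str = "balanced"
    probability_scores: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("svm_rbf", "random_forest", "gradient_boosted_trees"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if not self.grid:
            self.grid = {
                "svm_rbf": DEFAULT_SVM_GRID,
                "random_forest": DEFAULT_RF_GRID,
                "gradient_boosted_trees": DEFAULT_GBT_GRID,
            }[self.kind]

    def build(self):
        weighting = self.class_weighting if self.class_weighting != "none" else None
        if self.kind == "svm_rbf":
            clf = SVC(kernel="rbf", class_weight=weighting,
                      probability=self.probability_scores,
                      random_state=self.seed)
        elif self.kind == "random_forest":
            clf = RandomForestClassifier(class_weight=weighting,
                                         random_state=self.seed)
        else:
            from xgboost import XGBClassifier

            clf = XGBClassifier(eval_metric="logloss", random_state=self.seed,
                                n_jobs=1)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class MetricSet:
    accuracy: float
    recall: float
    specificity: float
    precision: float
    f1: float
    auc: float

    def as_dict(self):
        return {k: getattr(self, k) for k in
                ("accuracy", "recall", "specificity", "precision", "f1", "auc")}


def custom_folds(table: pd.DataFrame, n_majority_test: int = 7, rng=None):
    """Replica-aware folds: one per original minority case.

    Test set = the original + all rows with ``origin == "replica:<id>"`` +
    ``n_majority_test`` randomly chosen majority rows (disjoint across folds
    while the majority lasts); train = every other row.
    """
    if "origin" not in table.columns or "group" not in table.columns:
        raise ValueError("table must carry 'origin' and 'group' provenance columns")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    originals = table.index[
        (table["group"] == POSITIVE) & (table["origin"] == "original")
    ].tolist()
    if not originals:
        raise ValueError("no original minority rows found")
    majority = table.index[table["group"] == NEGATIVE].to_numpy()
    shuffled = majority[rng.permutation(majority.size)]

    folds = []
    for i, orig in enumerate(originals):
        replicas = table.index[table["origin"] == f"replica:{orig}"].tolist()
        start = i * n_majority_test
        if start + n_majority_test <= shuffled.size:
            maj_test = shuffled[start : start + n_majority_test]
        else:  # majority exhausted: re-draw among all majority rows
            maj_test = rng.choice(majority, size=n_majority_test, replace=False)
        test_ids = [orig] + replicas + list(maj_test)
        train_ids = [ix for ix in table.index if ix not in set(test_ids)]
        folds.append((train_ids, test_ids))
    return folds


def stratified_folds(table: pd.DataFrame, n_splits: int = 20, rng=None):
    """Stratified k-fold over the table rows (proportion-preserving)."""
    y = (table["group"] == POSITIVE).to_numpy()
    n_minority = int(min(y.sum(), (~y).sum()))
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if n_splits > n_minority:
        raise ValueError("n_splits exceeds the minority class count")
    seed = int(np.random.default_rng(rng).integers(0, 2**31 - 1))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    idx = table.index.to_numpy()
    return [(list(idx[tr]), list(idx[te])) for tr, te in skf.split(idx, y)]


def fit_predict(spec: ClassifierSpec, train: pd.DataFrame, test: pd.DataFrame,
                inner_splits: int = 3):
    """Grid-search on the training rows, fit, and score the test rows.

    Returns ``(labels, scores)``: hard labels and the positive-class
    probability (or margin when probabilities are disabled).
    """
    feature_cols = [c for c in train.columns if c not in META_COLUMNS]
    X_tr = train[feature_cols].to_numpy(dtype=float)
    y_tr = (train["group"] == POSITIVE).to_numpy(dtype=int)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set must contain both classes")
    X_te = test[feature_cols].to_numpy(dtype=float)

    inner = StratifiedKFold(n_splits=inner_splits, shuffle=True,
                            random_state=spec.seed)
    search = GridSearchCV(spec.build(), spec.grid, cv=inner, scoring="f1",
                          n_jobs=1)
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecates SVC(probability=True); the probability
        # scores are part of this estimator's contract, so keep them quiet.
        warnings.filterwarnings("ignore", category=FutureWarning)
        warnings.filterwarnings("ignore", category=UserWarning)
        search.fit(X_tr, y_tr)
    model = search.best_estimator_
    labels = model.predict(X_te)
    if hasattr(model, "predict_proba") and spec.probability_scores:
        scores = model.predict_proba(X_te)[:, 1]
    else:
        scores = model.decision_function(X_te)
    return labels, scores


def metrics(y_true, y_pred, scores) -> MetricSet:
    """Confusion-matrix metrics plus trapezoidal ROC AUC (positive = acidemic)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.size == 0 or y_true.size != y_pred.size or y_true.size != scores.size:
        raise ValueError("inputs must be non-empty and of equal length")
    if not set(np.unique(y_true)) <= {0, 1} or not set(np.unique(y_pred)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = y_true.size

    def safe(num, den):
        return num / den if den > 0 else 0.0

    precision = safe(tp, tp + fp)
    recall = safe(tp, tp + fn)
    f1 = safe(2 * precision * recall, precision + recall)
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    else:
        auc = float("nan")
    return MetricSet(
        accuracy=safe(tp + tn, n), recall=recall,
        specificity=safe(tn, tn + fp), precision=precision, f1=f1, auc=auc,
    )


def evaluate_feature_set(table: pd.DataFrame, spec: ClassifierSpec, folds,
                         collinearity_threshold: float = 0.5,
                         aggregate: str = "pooled"):
    """Run one feature-set table through the folds.

    Per fold: collinearity filter on train, grid-search fit, test prediction.
    ``aggregate="pooled"`` (the contract) pools all test predictions and
    computes one MetricSet; ``"averaged"`` averages per-fold metrics.
    Returns ``(MetricSet, roc_points_dataframe)``.
    """
    all_true, all_pred, all_scores = [], [], []
    per_fold = []
    for train_ids, test_ids in folds:
        kept = collinearity_filter(table, threshold=collinearity_threshold,
                                   train_index=train_ids)
        cols = kept + [c for c in META_COLUMNS if c in table.columns]
        train = table.loc[train_ids, cols]
        test = table.loc[test_ids, cols]
        labels, scores = fit_predict(spec, train, test)
        y_true = (test["group"] == POSITIVE).to_numpy(dtype=int)
        all_true.append(y_true)
        all_pred.append(labels)
        all_scores.append(scores)
        if aggregate == "averaged":
            per_fold.append(metrics(y_true, labels, scores))
    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    scores = np.concatenate(all_scores)
    if aggregate == "averaged":
        vals = {k: float(np.mean([getattr(m, k) for m in per_fold]))
                for k in per_fold[0].as_dict()}
        result = MetricSet(**vals)
    else:
        result = metrics(y_true, y_pred, scores)
    fpr, tpr, thr = roc_curve(y_true, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return result, roc


def run_tests(table: pd.DataFrame, test_ids=None, specs=None, seed: int = 0,
              cv: str = "custom", n_splits: int = 20,
              collinearity_threshold: float = 0.5):
    """Evaluate feature sets A..I for each classifier.

    Returns ``(results, rocs)``: a DataFrame indexed by (classifier, metric)
    with one column per test, and a dict of ROC-point DataFrames keyed by
    (classifier kind, test id).  The same folds are reused across tests and
    classifiers so comparisons share the data split.
    """
    test_ids = list(test_ids) if test_ids is not None else list("ABCDEFGHI")
    specs = specs if specs is not None else [ClassifierSpec(seed=seed)]
    rng = np.random.default_rng(seed)
    if cv == "custom":
        folds = custom_folds(table, rng=rng)
    elif cv == "stratified":
        folds = stratified_folds(table, n_splits=n_splits, rng=rng)
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")

    rows, rocs = {}, {}
    for spec in specs:
        for tid in test_ids:
            sub = select_feature_set(table, tid)
            mset, roc = evaluate_feature_set(
                sub, spec, folds, collinearity_threshold=collinearity_threshold)
            rows[(spec.kind, tid)] = mset.as_dict()
            rocs[(spec.kind, tid)] = roc
    results = pd.DataFrame(rows).T
    results.index.names = ["classifier", "test"]
    results = results.unstack("test").swaplevel(axis=1).sort_index(axis=1)
    # shape: rows = classifier, columns = (test, metric)
    return results, rocs
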