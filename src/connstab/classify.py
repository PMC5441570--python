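"""Leave-one-subject-out classification with per-fold filter feature selection.

Every fold holds out all runs of one subject; features are ranked by the
two-sample t-test on the *training* rows only, so no information about the
held-out subject leaks into feature selection ("double-dipping"). A
``double_dip_comparison`` helper quantifies the optimistic bias incurred when
ranking is instead done once on all rows.

The classifier families are standard scikit-learn estimators with fixed,
sensible default hyperparameters; the bespoke contract here is fold
construction, per-fold ranking, and aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import CohortSample
from .features import FeatureMatrix
from .stability import top_k
from .univariate import two_sample_ttest

__all__ = [
    "CLASSIFIER_FAMILIES",
    "FoldSpec",
    "ClassificationResult",
    "make_loso_folds",
    "run_cv",
    "double_dip_comparison",
    "chance_level",
    "DiagnosisCV",
]


def _make_classifier(family: str, seed: int = 0, **hyperparams):
    factories = {
        "nearest_neighbors": lambda: KNeighborsClassifier(
            n_neighbors=hyperparams.get("n_neighbors", 5)
        ),
        "linear_svm": lambda: SVC(kernel="linear", C=hyperparams.get("C", 1.0)),
        "rbf_svm": lambda: SVC(kernel="rbf", C=hyperparams.get("C", 1.0), gamma="scale"),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=hyperparams.get("n_estimators", 100), random_state=seed
        ),
        "logistic_regression": lambda: LogisticRegression(
            C=hyperparams.get("C", 1.0), max_iter=2000
        ),
        "gaussian_nb": lambda: GaussianNB(),
        "lda": lambda: LinearDiscriminantAnalysis(),
    }
    if family not in factories:
        raise ValueError(f"unknown classifier family {family!r}")
    return factories[family]()


CLASSIFIER_FAMILIES = (
    "nearest_neighbors",
    "linear_svm",
    "rbf_svm",
    "decision_tree",
    "random_forest",
    "logistic_regression",
    "gaussian_nb",
    "lda",
)


@dataclass(frozen=True)
class FoldSpec:
    """One leave-one-subject-out fold: all runs of the test subject held out."""

    test_subject: str
    test_rows: np.ndarray
    train_rows: np.ndarray


def make_loso_folds(samples: list[CohortSample]) -> list[FoldSpec]:
    """One fold per subject, in order of first appearance."""
    subject_ids = np.array([s.subject_id for s in samples])
    seen: list[str] = []
    for sid in subject_ids:
        if sid not in seen:
            seen.append(sid)
    if len(seen) < 2:
        raise ValueError("need at least 2 subjects for leave-one-subject-out CV")
    folds = []
    all_rows = np.arange(len(samples))
    for sid in seen:
        test = all_rows[subject_ids == sid]
        if len(test) == 0:
            raise ValueError(f"subject {sid} has no runs")
        train = all_rows[subject_ids != sid]
        folds.append(FoldSpec(test_subject=sid, test_rows=test, train_rows=train))
    return folds


@dataclass
class ClassificationResult:
    """Per-(k, fold) CV outputs and per-k aggregates.

    Error is the fraction of misclassified test runs; FP/FN rates take
    "patient" as the positive class, each on its own denominator within the
    fold's test set.
    """

    classifier_family: str
    k_grid: list[int]
    fold_subjects: list[str]
    per_fold_error: dict[int, np.ndarray]
    per_fold_fp: dict[int, np.ndarray]
    per_fold_fn: dict[int, np.ndarray]
    per_fold_selected: dict[int, list[np.ndarray]]
    per_fold_predictions: dict[int, list[np.ndarray]]

    def mean_error(self, k: int) -> float:
        return float(np.mean(self.per_fold_error[k]))

    @property
    def mean_errors(self) -> dict[int, float]:
        return {k: self.mean_error(k) for k in self.k_grid}

    @property
    def best_k(self) -> int:
        """k with the lowest mean error over all folds (computed after CV)."""
        errs = self.mean_errors
        return min(self.k_grid, key=lambda k: (errs[k], k))

    def frame(self) -> pd.DataFrame:
        rows = []
        for k in self.k_grid:
            rows.append(
                {
                    "k": k,
                    "mean_error": self.mean_error(k),
                    "mean_fp": float(np.nanmean(self.per_fold_fp[k])),
                    "mean_fn": float(np.nanmean(self.per_fold_fn[k])),
                }
            )
        return pd.DataFrame(rows)


def _fold_rates(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    err = float(np.mean(pred != truth))
    pos = truth
    neg = ~truth
    fp = float(np.mean(pred[neg])) if neg.any() else np.nan
    fn = float(np.mean(~pred[pos])) if pos.any() else np.nan
    return err, fp, fn


def run_cv(
    fm: FeatureMatrix,
    is_patient: np.ndarray | None,
    folds: list[FoldSpec],
    classifier_family: str,
    k_grid: list[int],
    seed: int = 0,
    **hyperparams,
) -> ClassificationResult:
    """LOSO CV with per-fold t-test ranking and top-k filter selection.

    For each fold: rank features by two-sample t-test on the training rows
    only; for each k fit the classifier on the top-k training columns and
    predict the held-out runs. k values exceeding the feature count are
    skipped with a warning.
    """
    if is_patient is None:
        is_patient = fm.is_patient
    y = np.asarray(is_patient, dtype=bool)
    X = fm.values
    valid_k = []
    for k in k_grid:
        if k > fm.n_features:
            warnings.warn(f"k={k} exceeds feature count {fm.n_features}; skipped")
        else:
            valid_k.append(int(k))
    res = ClassificationResult(
        classifier_family=classifier_family,
        k_grid=valid_k,
        fold_subjects=[f.test_subject for f in folds],
        per_fold_error={k: np.empty(len(folds)) for k in valid_k},
        per_fold_fp={k: np.empty(len(folds)) for k in valid_k},
        per_fold_fn={k: np.empty(len(folds)) for k in valid_k},
        per_fold_selected={k: [] for k in valid_k},
        per_fold_predictions={k: [] for k in valid_k},
    )
    for fi, fold in enumerate(folds):
        ranking = two_sample_ttest(X[fold.train_rows], y[fold.train_rows])
        order = np.argsort(ranking.pvalue, kind="stable")
        for k in valid_k:
            sel = order[:k]
            clf = _make_classifier(classifier_family, seed=seed, **hyperparams)
            clf.fit(X[np.ix_(fold.train_rows, sel)], y[fold.train_rows])
            pred = clf.predict(X[np.ix_(fold.test_rows, sel)]).astype(bool)
            err, fp, fn = _fold_rates(pred, y[fold.test_rows])
            res.per_fold_error[k][fi] = err
            res.per_fold_fp[k][fi] = fp
            res.per_fold_fn[k][fi] = fn
            res.per_fold_selected[k].append(sel)
            res.per_fold_predictions[k].append(pred)
    return res


def double_dip_comparison(
    fm: FeatureMatrix,
    is_patient: np.ndarray | None,
    folds: list[FoldSpec],
    classifier_family: str,
    k: int,
    seed: int = 0,
    **hyperparams,
) -> tuple[float, float]:
    """Mean CV accuracy with proper per-fold ranking vs. double-dipped ranking.

    "Double-dipped" ranks the features once on ALL rows (test subjects
    included) and then runs the same CV — the protocol that inflates apparent
    accuracy on noise.
    """
    if is_patient is None:
        is_patient = fm.is_patient
    y = np.asarray(is_patient, dtype=bool)
    proper = run_cv(fm, y, folds, classifier_family, [k], seed=seed, **hyperparams)
    proper_acc = 1.0 - proper.mean_error(k)

    global_rank = two_sample_ttest(fm.values, y)
    sel = top_k(global_rank.pvalue, k)
    accs = []
    for fold in folds:
        clf = _make_classifier(classifier_family, seed=seed, **hyperparams)
        clf.fit(fm.values[np.ix_(fold.train_rows, sel)], y[fold.train_rows])
        pred = clf.predict(fm.values[np.ix_(fold.test_rows, sel)]).astype(bool)
        accs.append(float(np.mean(pred == y[fold.test_rows])))
    return proper_acc, float(np.mean(accs))


def chance_level(labels, subject_ids=None) -> float:
    """Majority-class proportion as a percentage.

    With ``subject_ids`` given, labels are first collapsed to one per subject
    (the subject-level chance rate quoted alongside LOSO accuracies).
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    if subject_ids is not None:
        subject_ids = np.asarray(subject_ids)
        _, first = np.unique(subject_ids, return_index=True)
        labels = labels[first]
    _, counts = np.unique(labels, return_counts=True)
    return 100.0 * counts.max() / counts.sum()


class DiagnosisCV:
    """Patient-vs-control LOSO classification model over a feature matrix."""

    def __init__(
        self,
        fm: FeatureMatrix,
        classifier_family: str = "linear_svm",
        k_grid: list[int] | None = None,
        seed: int = 0,
        **hyperparams,
    ):
        self.fm = fm
        self.classifier_family = classifier_family
        self.k_grid = k_grid if k_grid is not None else [10, 30, 100]
        self.seed = seed
        self.hyperparams = hyperparams
        self.folds = make_loso_folds(fm.samples)

    def fit(self) -> "DiagnosisResults":
        result = run_cv(
            self.fm,
            self.fm.is_patient,
            self.folds,
            self.classifier_family,
            self.k_grid,
            seed=self.seed,
            **self.hyperparams,
        )
        return DiagnosisResults(self, result)


class DiagnosisResults:
    def __init__(self, model: DiagnosisCV, result: ClassificationResult):
        self.model = model
        self.result = result

    @property
    def best_k(self) -> int:
        return self.result.best_k

    @property
    def best_error(self) -> float:
        return self.result.mean_error(self.best_k)

    @property
    def chance(self) -> float:
        return chance_level(self.model.fm.is_patient, self.model.fm.subject_ids)

    def frame(self) -> pd.DataFrame:
        return self.result.frame()

    def summary(self) -> str:
        lines = [
            f"LOSO diagnosis CV ({self.model.classifier_family}, "
            f"{len(self.model.folds)} folds)",
            f"  feature type: {self.model.fm.feature_type} "
            f"({self.model.fm.n_features} features)",
            f"  k grid: {self.result.k_grid}",
            f"  best k: {self.best_k}  mean error: {100 * self.best_error:.1f}%  "
            f"accuracy: {100 * (1 - self.best_error):.1f}%",
            f"  chance level (subject majority class): {self.chance:.1f}%",
        ]
        return "\n".join(lines)
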