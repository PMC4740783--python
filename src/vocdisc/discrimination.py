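"""Cross-validated stimulus classification of per-trial responses.

Each trial response (an EPSP-smoothed trace segment or a feature vector) is
assigned to one of the N_voc stimulus classes under stratified 10-fold
cross-validation with 10% test data.  Per fold, a column-normalised
confusion matrix Conf (rows = assigned class, columns = presented class,
entries in percent) is accumulated; the diagonal averaged over folds gives
the per-vocalization correct classification

    CC(k) = (1 / N_xval) * sum_x Conf_x(k, k),

and their mean over classes the overall correct classification

    CC = (1 / N_voc) * sum_k CC(k).

The classification error is the standard deviation of the fold-wise overall
accuracy.  The flagship decoder is the correlation template: a test trace
joins the class whose training traces it correlates with most strongly on
average; LDA, Gaussian naive Bayes, 1-nearest-neighbour and a minimum
squared-rate-difference rule cover the comparison grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "CrossValPlan",
    "ClassificationResult",
    "assign_corr_template",
    "crossval_assign",
    "crossval_classify",
    "classify_feature_matrix",
    "CLASSIFIER_METHODS",
]

CLASSIFIER_METHODS = (
    "corr-template",
    "max",
    "lda",
    "naive-bayes",
    "nearest-neighbor",
    "min-sq-rate",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classification rule plus method options."""

    method: str = "corr-template"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in CLASSIFIER_METHODS:
            raise ValueError(
                f"unknown classifier {self.method!r}; choose from {CLASSIFIER_METHODS}"
            )


@dataclass(frozen=True)
class CrossValPlan:
    """Stratified k-fold plan: every fold tests n_trials/n_folds trials per class."""

    n_folds: int = 10
    seed: int = 0

    @property
    def test_fraction(self) -> float:
        return 1.0 / self.n_folds

    def folds(self, labels: np.ndarray):
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.seed)
        yield from skf.split(np.zeros((labels.size, 1)), labels)


@dataclass(frozen=True)
class ClassificationResult:
    """Fold-averaged confusion matrix and the derived CC statistics (percent)."""

    conf_mean: np.ndarray  # n_voc x n_voc, rows assigned, columns presented
    cc_per_voc: np.ndarray  # CC(k), percent
    cc: float  # overall CC, percent
    cc_sd: float  # SD of fold-wise overall accuracy, percent
    classes: tuple  # class labels, column/row order of conf_mean
    fold_accuracy: np.ndarray  # per-fold overall accuracy, percent
    fold_cc_per_voc: np.ndarray | None = None  # (n_folds, n_voc) fold diagonals

    def cc_per_voc_sd(self) -> np.ndarray:
        """Across-fold SD of each class's diagonal entry (percent)."""
        if self.fold_cc_per_voc is None:
            raise ValueError("fold-wise diagonals were not recorded")
        return self.fold_cc_per_voc.std(axis=0, ddof=1)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "classes": [str(c) for c in self.classes],
            "cc": self.cc,
            "cc_sd": self.cc_sd,
            "cc_per_voc": self.cc_per_voc.tolist(),
            "conf_mean": self.conf_mean.tolist(),
            "fold_accuracy": self.fold_accuracy.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# correlation-template decoder


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit deviation norm; zero-variance rows -> 0.

    With this normalisation the matrix product of standardised rows is
    exactly the Pearson correlation, and zero-variance traces correlate 0
    with everything (the degenerate-trace convention).
    """
    x = np.asarray(x, dtype=float)
    d = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    flat = norms[:, 0] == 0
    if np.any(flat):
        logger.warning("%d zero-variance trace(s) in correlation decoding", flat.sum())
    norms[flat, 0] = 1.0
    d /= norms
    d[flat] = 0.0
    return d


def _mean_class_correlation(test: np.ndarray, train: np.ndarray,
                            train_labels: np.ndarray,
                            classes: np.ndarray) -> np.ndarray:
    """(n_test x n_classes) mean correlation of each test row with each class."""
    ct = _standardize_rows(test) @ _standardize_rows(train).T
    return np.stack(
        [ct[:, train_labels == c].mean(axis=1) for c in classes], axis=1
    )


def assign_corr_template(test: np.ndarray, training: np.ndarray,
                         training_labels: np.ndarray) -> np.ndarray:
    """Assign each test trace to the class of maximal mean correlation.

    Ties (including the all-zero test trace, which correlates 0 with every
    class) resolve to the lowest class index, deterministically.
    """
    test = np.atleast_2d(np.asarray(test, dtype=float))
    training = np.asarray(training, dtype=float)
    training_labels = np.asarray(training_labels)
    classes = np.unique(training_labels)
    if test.shape[1] != training.shape[1]:
        raise ValueError("test and training segment lengths differ")
    scores = _mean_class_correlation(test, training, training_labels, classes)
    return classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# per-fold assignment for the remaining methods


def _assign_fold(method: str, params: dict, train: np.ndarray,
                 train_labels: np.ndarray, test: np.ndarray) -> np.ndarray:
    classes = np.unique(train_labels)
    if method in ("corr-template", "max"):
        return assign_corr_template(test, train, train_labels)
    if method == "min-sq-rate":
        # class minimising the mean (over that class's training trials)
        # squared Euclidean distance in rate space
        d2 = np.stack(
            [
                ((test[:, None, :] - train[None, train_labels == c, :]) ** 2)
                .sum(axis=2)
                .mean(axis=1)
                for c in classes
            ],
            axis=1,
        )
        return classes[np.argmin(d2, axis=1)]
    if method == "naive-bayes":
        clf = GaussianNB()
    elif method == "nearest-neighbor":
        clf = KNeighborsClassifier(n_neighbors=1)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(f"unknown classifier {method!r}")
    clf.fit(train, train_labels)
    return clf.predict(test)


def _fit_lda_safely(train, train_labels, test, params):
    try:
        clf = LinearDiscriminantAnalysis(solver=params.get("solver", "lsqr"))
        clf.fit(train, train_labels)
        return clf.predict(test)
    except np.linalg.LinAlgError:
        logger.warning("singular LDA covariance; refitting with shrinkage")
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(train, train_labels)
        return clf.predict(test)


# ---------------------------------------------------------------------------
# cross-validation engine


def crossval_assign(labels: np.ndarray, plan: CrossValPlan,
                    assign) -> ClassificationResult:
    """Generic stratified cross-validation with a caller-supplied rule.

    ``assign(train_idx, test_idx) -> predicted labels`` is called once per
    fold.  Per fold a column-normalised (percent) confusion matrix is
    accumulated; the fold-averaged diagonal gives CC(k), their mean the
    overall CC, and the SD of fold-wise overall accuracy the error bar.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < plan.n_folds):
        raise ValueError(
            f"every class needs >= {plan.n_folds} trials for {plan.n_folds}-fold "
            "stratified cross-validation"
        )
    n_voc = classes.size
    class_index = {c: i for i, c in enumerate(classes)}

    conf_folds = []
    fold_acc = []
    for train_idx, test_idx in plan.folds(labels):
        pred = np.asarray(assign(train_idx, test_idx))
        true = labels[test_idx]
        conf = np.zeros((n_voc, n_voc))
        for p, t in zip(pred, true):
            conf[class_index[p], class_index[t]] += 1.0
        col = conf.sum(axis=0)
        if np.any(col == 0):
            raise ValueError("a class is missing from a test fold; check the plan")
        conf = 100.0 * conf / col  # column-normalised percentages
        conf_folds.append(conf)
        fold_acc.append(100.0 * np.mean(pred == true))

    conf_folds = np.asarray(conf_folds)
    conf_mean = conf_folds.mean(axis=0)
    cc_per_voc = conf_mean.diagonal().copy()
    fold_acc = np.asarray(fold_acc)
    return ClassificationResult(
        conf_mean=conf_mean,
        cc_per_voc=cc_per_voc,
        cc=float(cc_per_voc.mean()),
        cc_sd=float(fold_acc.std(ddof=1)),
        classes=tuple(classes.tolist()),
        fold_accuracy=fold_acc,
        fold_cc_per_voc=np.stack([c.diagonal() for c in conf_folds]),
    )


def crossval_classify(responses: np.ndarray, labels: np.ndarray,
                      clf: ClassifierSpec | None = None,
                      plan: CrossValPlan | None = None) -> ClassificationResult:
    """Stratified cross-validated classification of per-trial responses.

    ``responses`` is an (n_trials_total x n_features) array — EPSP-trace
    segments for the correlation template, feature vectors otherwise.
    Classes are ordered by ``np.unique(labels)``; that order indexes the
    confusion matrix and is the tie-break order ("lowest class index").
    """
    clf = clf or ClassifierSpec()
    plan = plan or CrossValPlan()
    responses = np.asarray(responses, dtype=float)
    labels = np.asarray(labels)
    if responses.ndim != 2 or responses.shape[0] != labels.size:
        raise ValueError("responses must be (n_trials, n_features) matching labels")

    def assign(train_idx, test_idx):
        if clf.method == "lda":
            return _fit_lda_safely(responses[train_idx], labels[train_idx],
                                   responses[test_idx], clf.params)
        return _assign_fold(clf.method, clf.params, responses[train_idx],
                            labels[train_idx], responses[test_idx])

    return crossval_assign(labels, plan, assign)


def classify_feature_matrix(features: np.ndarray, labels: np.ndarray,
                            clf: ClassifierSpec, plan: CrossValPlan | None = None,
                            ) -> ClassificationResult:
    """Cross-validated classification of feature vectors (rate / spectral kinds).

    Same contract as :func:`crossval_classify`; exists as the named entry
    point for the feature-based arms of the (data type, feature, classifier)
    comparison grid.
    """
    return crossval_classify(features, labels, clf=clf, plan=plan)
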