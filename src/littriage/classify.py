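"""Ten-classifier tournament, five-fold model selection, ranked classification.

Rather than committing to one learner, the pipeline trains ten families —
support vector machine, elastic-net logistic regression (glmnet-style),
maximum entropy (multinomial logistic), scaled linear discriminant analysis,
bagging, boosting, random forest, k-nearest neighbour, a single decision
tree, and naive Bayes — on identical stratified five-fold splits and keeps
the one with the best mean cross-validated accuracy. Corpora differ in size
and separability, and no single family dominates across them.

All learners are scikit-learn estimators behind a uniform
probability-of-positive interface; margin-only learners (SVM) are passed
through a monotone logistic link fitted on training decision values, so
ranking is exact and calibration best-effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .corpus_io import Label
from .errors import SingleClassInput, TooFewDocuments, VocabularyMismatch
from .features import DocumentTermMatrix, top_k_columns

logger = logging.getLogger(__name__)


class Algorithm(Enum):
    SVM = "SVM"
    GLMNET = "GLMNET"
    MAXENT = "MAXENT"
    SLDA = "SLDA"
    BAGGING = "BAGGING"
    BOOSTING = "BOOSTING"
    RANDOM_FOREST = "RANDOM_FOREST"
    KNN = "KNN"
    TREE = "TREE"
    NAIVE_BAYES = "NAIVE_BAYES"


@dataclass(frozen=True)
class ClassifierSpec:
    """One tournament entrant; ``priority`` breaks mean-accuracy ties
    (lower number wins; the default roster is ordered 1-10)."""

    name: Algorithm
    hyperparameters: dict = field(default_factory=dict)
    priority: int = 0

    def __hash__(self) -> int:
        return hash((self.name, self.priority))


def default_roster() -> list[ClassifierSpec]:
    """All ten algorithms with pinned default hyperparameters."""
    defaults: list[tuple[Algorithm, dict]] = [
        (Algorithm.SVM, {"C": 1.0}),
        (Algorithm.GLMNET, {"alpha": 1e-4, "l1_ratio": 0.5}),
        (Algorithm.MAXENT, {"C": 1.0}),
        (Algorithm.SLDA, {}),
        (Algorithm.BAGGING, {"n_estimators": 50}),
        (Algorithm.BOOSTING, {"n_estimators": 50}),
        (Algorithm.RANDOM_FOREST, {"n_estimators": 100}),
        (Algorithm.KNN, {"n_neighbors": 5}),
        (Algorithm.TREE, {}),
        (Algorithm.NAIVE_BAYES, {"alpha": 1.0}),
    ]
    return [
        ClassifierSpec(name, hp, priority=i + 1)
        for i, (name, hp) in enumerate(defaults)
    ]


class _DenseTransformer(BaseEstimator):
    """Densify sparse input for estimators requiring dense arrays."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return X.toarray() if sp.issparse(X) else np.asarray(X)

    def fit_transform(self, X, y=None):
        return self.transform(X)


def _build_estimator(spec: ClassifierSpec, seed: int):
    hp = spec.hyperparameters
    name = spec.name
    if name is Algorithm.SVM:
        return LinearSVC(C=hp.get("C", 1.0), random_state=seed, max_iter=5000)
    if name is Algorithm.GLMNET:
        # elastic-net-penalised logistic regression, glmnet-style
        return SGDClassifier(
            loss="log_loss",
            penalty="elasticnet",
            alpha=hp.get("alpha", 1e-4),
            l1_ratio=hp.get("l1_ratio", 0.5),
            max_iter=2000,
            tol=1e-4,
            random_state=seed,
        )
    if name is Algorithm.MAXENT:
        return LogisticRegression(C=hp.get("C", 1.0), max_iter=2000)
    if name is Algorithm.SLDA:
        # scale features, then linear discriminant analysis; the SVD solver
        # tolerates the singular covariances of wide text matrices
        return Pipeline(
            [
                ("dense", _DenseTransformer()),
                ("scale", StandardScaler()),
                ("lda", LinearDiscriminantAnalysis(solver="svd")),
            ]
        )
    if name is Algorithm.BAGGING:
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=hp.get("n_estimators", 50),
            random_state=seed,
        )
    if name is Algorithm.BOOSTING:
        return AdaBoostClassifier(
            n_estimators=hp.get("n_estimators", 50), random_state=seed
        )
    if name is Algorithm.RANDOM_FOREST:
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=seed, n_jobs=1
        )
    if name is Algorithm.KNN:
        return KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
    if name is Algorithm.TREE:
        return DecisionTreeClassifier(random_state=seed)
    if name is Algorithm.NAIVE_BAYES:
        return MultinomialNB(alpha=hp.get("alpha", 1.0))
    raise ValueError(f"unknown algorithm {name}")


class _Model:
    """Fitted estimator + probability-of-positive interface.

    ``classes`` are 0 (negative) / 1 (positive). For estimators without
    predict_proba, decision scores are mapped through a 1-d logistic link
    fitted on the training decision values (monotone, so ranks are exact).
    """

    def __init__(self, spec: ClassifierSpec, seed: int):
        self.spec = spec
        self.est = _build_estimator(spec, seed)
        self._link: LogisticRegression | None = None

    def fit(self, X, y: np.ndarray) -> "_Model":
        self.est.fit(X, y)
        if not hasattr(self.est, "predict_proba"):
            scores = self.est.decision_function(X).reshape(-1, 1)
            link = LogisticRegression(max_iter=1000)
            if len(np.unique(y)) == 2 and len(np.unique(scores)) > 1:
                link.fit(scores, y)
                self._link = link
        return self

    def predict_proba_positive(self, X) -> np.ndarray:
        if hasattr(self.est, "predict_proba"):
            proba = self.est.predict_proba(X)
            pos_col = list(self.est.classes_).index(1)
            return proba[:, pos_col]
        scores = self.est.decision_function(X).reshape(-1, 1)
        if self._link is not None:
            return self._link.predict_proba(scores)[:, 1]
        # degenerate training: fall back to a sigmoid of the raw margin
        return 1.0 / (1.0 + np.exp(-scores.ravel()))


@dataclass
class SpecResult:
    spec: ClassifierSpec
    fold_accuracies: list[float]
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    mean_f1: float
    failures: int = 0


@dataclass
class TournamentResult:
    """Per-algorithm cross-validation metrics and the selected winner."""

    results: list[SpecResult]
    winner: ClassifierSpec
    folds: int
    seed: int

    def result_for(self, name: Algorithm) -> SpecResult:
        return next(r for r in self.results if r.spec.name is name)

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "seed": self.seed,
            "winner": self.winner.name.value,
            "algorithms": [
                {
                    "name": r.spec.name.value,
                    "priority": r.spec.priority,
                    "hyperparameters": r.spec.hyperparameters,
                    "fold_accuracies": r.fold_accuracies,
                    "mean_accuracy": r.mean_accuracy,
                    "mean_sensitivity": r.mean_sensitivity,
                    "mean_specificity": r.mean_specificity,
                    "mean_f1": r.mean_f1,
                    "failed_folds": r.failures,
                }
                for r in self.results
            ],
        }


def labels_to_binary(labels: list[Label]) -> np.ndarray:
    """POSITIVE -> 1, NEGATIVE -> 0."""
    return np.array([1 if lab is Label.POSITIVE else 0 for lab in labels])


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float, float]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    acc = (tp + tn) / len(y_true)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return acc, sens, spec, f1


def run_tournament(
    x: DocumentTermMatrix,
    labels: list[Label],
    roster: list[ClassifierSpec] | None = None,
    folds: int = 5,
    seed: int = 0,
    select_k: int | None = None,
) -> TournamentResult:
    """Stratified k-fold tournament over the roster; winner by mean accuracy.

    Every spec sees identical folds. A spec that fails to train on a fold
    scores 0 for that fold (logged). Mean-accuracy ties go to the lower
    priority number, i.e. the earlier algorithm in the canonical listing.

    When ``select_k`` is given, the Mann-Whitney term selection is re-run
    inside every fold on that fold's training rows only and both splits are
    restricted to those columns. With far more terms than documents,
    selecting on the full label vector before cross-validating leaks label
    information into the folds and inflates the CV estimate, so the nested
    form is what the pipeline uses; pass ``select_k=None`` to evaluate an
    externally reduced matrix as-is.
    """
    if roster is None:
        roster = default_roster()
    y = labels_to_binary(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise SingleClassInput("training labels contain a single class")
    if counts.min() < folds:
        raise TooFewDocuments(
            f"smallest class has {counts.min()} documents < {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    # per-fold column restriction, shared by every spec (identical folds)
    if select_k is None:
        fold_cols: list[np.ndarray | None] = [None] * len(splits)
    else:
        fold_cols = [
            top_k_columns(
                x.values[train_idx], y[train_idx] == 1, select_k, x.vocabulary
            )
            for train_idx, _ in splits
        ]

    results: list[SpecResult] = []
    for spec in roster:
        accs, senss, specs_, f1s = [], [], [], []
        failures = 0
        for (train_idx, val_idx), cols in zip(splits, fold_cols):
            try:
                x_tr = x.values[train_idx]
                x_val = x.values[val_idx]
                if cols is not None:
                    x_tr = x_tr[:, cols]
                    x_val = x_val[:, cols]
                model = _Model(spec, seed).fit(x_tr, y[train_idx])
                proba = model.predict_proba_positive(x_val)
                y_pred = (proba >= 0.5).astype(int)
                acc, sens, spc, f1 = _fold_metrics(y[val_idx], y_pred)
            except Exception as exc:  # noqa: BLE001 - contract: score 0, log
                logger.warning("%s failed on a fold: %s", spec.name.value, exc)
                failures += 1
                acc = sens = spc = f1 = 0.0
            accs.append(acc)
            senss.append(sens)
            specs_.append(spc)
            f1s.append(f1)
        results.append(
            SpecResult(
                spec,
                accs,
                float(np.mean(accs)),
                float(np.mean(senss)),
                float(np.mean(specs_)),
                float(np.mean(f1s)),
                failures,
            )
        )

    winner = min(results, key=lambda r: (-r.mean_accuracy, r.spec.priority)).spec
    return TournamentResult(results, winner, folds, seed)


@dataclass
class ClassificationResult:
    """Ranked class assignments for the unlabeled corpus."""

    doc_ids: list[str]
    probability_positive: np.ndarray
    assigned: list[Label]
    ranks: list[int]  # 1-based rank within the assigned class, by confidence
    winner: ClassifierSpec
    tournament: TournamentResult | None = None

    def split_lists(self) -> tuple[list[int], list[int]]:
        """Indices of positive / negative documents, each sorted by
        descending confidence in the assigned class."""
        pos = [i for i, lab in enumerate(self.assigned) if lab is Label.POSITIVE]
        neg = [i for i, lab in enumerate(self.assigned) if lab is Label.NEGATIVE]
        pos.sort(key=lambda i: (-self.probability_positive[i], self.doc_ids[i]))
        neg.sort(key=lambda i: (self.probability_positive[i], self.doc_ids[i]))
        return pos, neg


def fit_and_classify(
    x_train: DocumentTermMatrix,
    labels: list[Label],
    x_test: DocumentTermMatrix,
    winner: ClassifierSpec,
    seed: int = 0,
    tournament: TournamentResult | None = None,
) -> ClassificationResult:
    """Retrain the winning spec on the full training matrix and rank the
    test documents by probability of the positive class.

    Assignment is POSITIVE iff p >= 0.5; each output list is ordered by
    descending confidence (ties broken by doc_id for determinism).
    """
    if x_train.vocabulary != x_test.vocabulary:
        raise VocabularyMismatch("train and test matrices must share columns")
    y = labels_to_binary(labels)
    model = _Model(winner, seed).fit(x_train.values, y)
    proba = np.clip(model.predict_proba_positive(x_test.values), 0.0, 1.0)
    assigned = [Label.POSITIVE if p >= 0.5 else Label.NEGATIVE for p in proba]

    result = ClassificationResult(
        list(x_test.doc_ids), proba, assigned, [0] * len(proba), winner, tournament
    )
    pos, neg = result.split_lists()
    for rank, i in enumerate(pos, start=1):
        result.ranks[i] = rank
    for rank, i in enumerate(neg, start=1):
        result.ranks[i] = rank
    return result
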