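"""Evaluation: confusion metrics, ROC/AUC, learning curves, imbalance sweeps.

AUC is computed from the rank statistic (the Mann-Whitney identity
AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg) with midranks for tied
scores) and cross-checked internally against trapezoidal integration of the
ROC curve. Learning-curve and class-imbalance experiments subsample a
labeled training pool and score on a fixed held-out set, so curve noise
reflects training-set sampling only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .corpus_io import Label
from .errors import OddSize, RatioSumMismatch, SizeExceedsCorpus
from .features import (
    build_dtm,
    project_onto_vocabulary,
    restrict_to_terms,
    select_terms,
    tfidf_transform,
)
from .preprocess import TokenizedCorpus
from .classify import (
    ClassifierSpec,
    default_roster,
    fit_and_classify,
    labels_to_binary,
    run_tournament,
)

logger = logging.getLogger(__name__)


@dataclass
class MetricSet:
    """Confusion counts and derived rates at a fixed threshold, plus AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    f1_positive: float
    f1_negative: float
    auc: float | None  # None when truth is single-class

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1_positive": self.f1_positive,
            "f1_negative": self.f1_negative,
            "auc": self.auc,
        }


def rank_auc(truth: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank identity with midranks for ties."""
    pos = truth == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    ranks = rankdata(scores)
    r_pos = ranks[pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve_points(truth: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """ROC points (fpr, tpr, threshold), thresholds descending."""
    order = np.argsort(-scores, kind="stable")
    truth = truth[order]
    scores = scores[order]
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    tps = np.cumsum(truth == 1)
    fps = np.cumsum(truth == 0)
    # collapse tied thresholds: keep the last index of each distinct score
    distinct = np.r_[np.diff(scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thr = np.r_[np.inf, scores[distinct]]
    return np.column_stack([fpr, tpr, thr])


def trapezoid_auc(truth: np.ndarray, scores: np.ndarray) -> float:
    pts = roc_curve_points(truth, scores)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def binary_metrics(
    truth: list[Label] | np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
) -> MetricSet:
    """Confusion matrix at ``threshold`` plus rank-based AUC.

    With single-class truth the AUC is reported as None (undefined); the
    thresholded metrics are still computed.
    """
    y = (
        labels_to_binary(list(truth))
        if len(truth) and isinstance(truth[0], Label)
        else np.asarray(truth, dtype=int)
    )
    scores = np.asarray(scores, dtype=float)
    if len(y) != len(scores) or len(y) == 0:
        raise ValueError("truth and scores must be equal-length and non-empty")
    pred = (scores >= threshold).astype(int)
    tp = int(((y == 1) & (pred == 1)).sum())
    fp = int(((y == 0) & (pred == 1)).sum())
    tn = int(((y == 0) & (pred == 0)).sum())
    fn = int(((y == 1) & (pred == 0)).sum())
    acc = (tp + tn) / len(y)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1_pos = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    f1_neg = 2 * tn / (2 * tn + fn + fp) if 2 * tn + fn + fp else 0.0
    if len(np.unique(y)) < 2:
        logger.warning("single-class truth: AUC undefined")
        auc: float | None = None
    else:
        auc = rank_auc(y, scores)
        auc_trap = trapezoid_auc(y, scores)
        if abs(auc - auc_trap) > 1e-9:  # internal identity check, every run
            raise AssertionError(
                f"rank AUC {auc} != trapezoid AUC {auc_trap}"
            )
    return MetricSet(tp, fp, tn, fn, acc, sens, spec, f1_pos, f1_neg, auc)


@dataclass
class CurvePoint:
    """One x-position of a curve: per-seed metric values and their mean."""

    x: int
    values: list[float]
    mean: float
    reps: int

    @classmethod
    def from_values(cls, x: int, values: list[float]) -> "CurvePoint":
        return cls(x, values, float(np.mean(values)), len(values))


def _subcorpus(tc: TokenizedCorpus, idx: np.ndarray) -> TokenizedCorpus:
    return TokenizedCorpus(
        [tc.documents[i] for i in idx],
        [tc.tokens[i] for i in idx],
        tc.config,
    )


def _pipeline_scores(
    train: TokenizedCorpus,
    eval_set: TokenizedCorpus,
    top_terms: int,
    spec: ClassifierSpec | None,
    folds: int,
    seed: int,
) -> np.ndarray:
    """Features + (tournament or fixed spec) + classification scores on
    the held-out set. Mirrors the full pipeline's feature path."""
    counts = build_dtm(train)
    weighted = tfidf_transform(counts)
    selections = select_terms(weighted, train.labels, k=top_terms)
    kept = [s.term for s in selections if s.selected]
    x_train = restrict_to_terms(weighted, kept)
    if spec is None:
        spec = run_tournament(
            weighted, train.labels, folds=folds, seed=seed, select_k=top_terms
        ).winner
    x_eval = project_onto_vocabulary(eval_set, x_train.vocabulary, counts)
    result = fit_and_classify(x_train, train.labels, x_eval, spec, seed=seed)
    return result.probability_positive


def learning_curve(
    corpus: TokenizedCorpus,
    sizes: list[int],
    reps: int,
    seed: int,
    eval_set: TokenizedCorpus,
    spec: ClassifierSpec | None = None,
    top_terms: int = 1000,
    folds: int = 5,
) -> list[CurvePoint]:
    """Held-out accuracy as a function of balanced training-set size.

    For each size and rep, a balanced random subsample (size/2 per class) is
    drawn from ``corpus``, the full feature + classification pipeline runs,
    and accuracy is measured on the fixed ``eval_set``. ``spec=None`` runs
    the tournament at every point; passing a spec (e.g. GLMNET) fixes the
    learner, matching the elastic-net learning-curve protocol.
    """
    y = labels_to_binary(corpus.labels)
    y_eval = labels_to_binary(eval_set.labels)
    for size in sizes:
        if size > len(corpus):
            raise SizeExceedsCorpus(f"size {size} > corpus size {len(corpus)}")
        if size % 2:
            raise OddSize(f"size {size} is odd; balanced subsampling needs even")
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if sizes and max(sizes) // 2 > min(len(pos_idx), len(neg_idx)):
        raise SizeExceedsCorpus("a class is smaller than the largest size/2")
    # paired design: within a rep, subsamples are nested across sizes
    # (one permutation per class per rep; each size takes a prefix), so
    # consecutive curve points share training documents and size-to-size
    # noise largely cancels
    per_size_values: dict[int, list[float]] = {size: [] for size in sizes}
    for rep in range(reps):
        rng = np.random.default_rng([seed, rep])
        pos_perm = rng.permutation(pos_idx)
        neg_perm = rng.permutation(neg_idx)
        for size in sizes:
            half = size // 2
            idx = np.sort(np.concatenate([pos_perm[:half], neg_perm[:half]]))
            scores = _pipeline_scores(
                _subcorpus(corpus, idx), eval_set, top_terms, spec, folds,
                seed=int(rng.integers(2**31)),
            )
            per_size_values[size].append(binary_metrics(y_eval, scores).accuracy)
    return [CurvePoint.from_values(size, per_size_values[size]) for size in sizes]


def imbalance_experiment(
    corpus: TokenizedCorpus,
    total: int,
    ratios: list[tuple[int, int]],
    reps: int,
    seed: int,
    eval_set: TokenizedCorpus,
    spec: ClassifierSpec | None = None,
    top_terms: int = 1000,
    folds: int = 5,
) -> list[tuple[CurvePoint, CurvePoint]]:
    """Per-class F1 on a balanced held-out set as the training class ratio
    varies at fixed total size. Returns (F1_pos, F1_neg) curve points per
    ratio; x is the positive-class training count."""
    y = labels_to_binary(corpus.labels)
    y_eval = labels_to_binary(eval_set.labels)
    for n_pos, n_neg in ratios:
        if n_pos + n_neg != total:
            raise RatioSumMismatch(f"{n_pos}+{n_neg} != total {total}")
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if any(a > len(pos_idx) or b > len(neg_idx) for a, b in ratios):
        raise SizeExceedsCorpus("a ratio exceeds the per-class pool")
    # paired across ratios: one permutation per class per rep, each ratio
    # takes prefixes, so the balanced/imbalanced comparison is matched
    f1s: dict[tuple[int, int], tuple[list[float], list[float]]] = {
        r: ([], []) for r in ratios
    }
    for rep in range(reps):
        rng = np.random.default_rng([seed, rep])
        pos_perm = rng.permutation(pos_idx)
        neg_perm = rng.permutation(neg_idx)
        for n_pos, n_neg in ratios:
            idx = np.sort(np.concatenate([pos_perm[:n_pos], neg_perm[:n_neg]]))
            scores = _pipeline_scores(
                _subcorpus(corpus, idx), eval_set, top_terms, spec, folds,
                seed=int(rng.integers(2**31)),
            )
            m = binary_metrics(y_eval, scores)
            f1s[(n_pos, n_neg)][0].append(m.f1_positive)
            f1s[(n_pos, n_neg)][1].append(m.f1_negative)
    return [
        (
            CurvePoint.from_values(n_pos, f1s[(n_pos, n_neg)][0]),
            CurvePoint.from_values(n_pos, f1s[(n_pos, n_neg)][1]),
        )
        for n_pos, n_neg in ratios
    ]


def null_tournament_accuracies(
    corpus: TokenizedCorpus,
    top_terms: int = 1000,
    folds: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Mean CV accuracy of every roster algorithm on a corpus (used for
    null-calibration checks on no-signal synthetic data)."""
    counts = build_dtm(corpus)
    weighted = tfidf_transform(counts)
    tour = run_tournament(
        weighted, corpus.labels, default_roster(),
        folds=folds, seed=seed, select_k=top_terms,
    )
    return {r.spec.name.value: r.mean_accuracy for r in tour.results}
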