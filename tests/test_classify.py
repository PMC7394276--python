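"""Classifier tournament: roster, cross-validation, ranked classification."""

import numpy as np
import pytest

from littriage.classify import (
    Algorithm,
    ClassifierSpec,
    default_roster,
    fit_and_classify,
    labels_to_binary,
    run_tournament,
)
from littriage.corpus_io import Category, Corpus, Document, Label
from littriage.errors import SingleClassInput, TooFewDocuments, VocabularyMismatch
from littriage.features import (
    build_dtm,
    project_onto_vocabulary,
    restrict_to_terms,
    select_terms,
    tfidf_transform,
)
from littriage.preprocess import preprocess_corpus
from littriage.synthetic import GeneratorConfig, generate_corpus


def test_default_roster_has_all_ten_once():
    roster = default_roster()
    assert [s.priority for s in roster] == list(range(1, 11))
    assert {s.name for s in roster} == set(Algorithm)


@pytest.fixture(scope="module")
def easy_weighted(small_easy_tc):
    """Weighted training DTM of the separable synthetic corpus."""
    counts = build_dtm(small_easy_tc)
    return counts, tfidf_transform(counts), small_easy_tc.labels


class TestRunTournament:
    def test_separated_corpus_high_accuracy(self, easy_weighted):
        _, weighted, labels = easy_weighted
        tour = run_tournament(weighted, labels, folds=5, seed=0, select_k=200)
        best = max(r.mean_accuracy for r in tour.results)
        assert best >= 0.95
        assert tour.result_for(tour.winner.name).mean_accuracy == best

    def test_tie_break_prefers_lower_priority(self, easy_weighted):
        _, weighted, labels = easy_weighted
        # identical learner entered twice: identical folds give identical
        # accuracy, so the lower priority number must win
        roster = [
            ClassifierSpec(Algorithm.NAIVE_BAYES, {"alpha": 1.0}, priority=9),
            ClassifierSpec(Algorithm.NAIVE_BAYES, {"alpha": 1.0}, priority=2),
        ]
        tour = run_tournament(weighted, labels, roster, folds=5, seed=0)
        a, b = tour.results
        assert a.mean_accuracy == b.mean_accuracy
        assert tour.winner.priority == 2

    def test_single_class_raises(self, easy_weighted):
        _, weighted, _ = easy_weighted
        labels = [Label.POSITIVE] * weighted.shape[0]
        with pytest.raises(SingleClassInput):
            run_tournament(weighted, labels)

    def test_too_few_documents_raises(self, easy_weighted):
        _, weighted, labels = easy_weighted
        # relabel so only 3 documents are negative, below folds=5
        labels = [
            Label.NEGATIVE if i < 3 else Label.POSITIVE
            for i in range(len(labels))
        ]
        with pytest.raises(TooFewDocuments):
            run_tournament(weighted, labels, folds=5)

    def test_determinism_under_seed(self, easy_weighted):
        _, weighted, labels = easy_weighted
        roster = [
            ClassifierSpec(Algorithm.RANDOM_FOREST, {"n_estimators": 30}, 1),
            ClassifierSpec(Algorithm.GLMNET, {}, 2),
        ]
        t1 = run_tournament(weighted, labels, roster, folds=5, seed=3, select_k=100)
        t2 = run_tournament(weighted, labels, roster, folds=5, seed=3, select_k=100)
        for r1, r2 in zip(t1.results, t2.results):
            assert r1.fold_accuracies == r2.fold_accuracies
        assert t1.winner == t2.winner

    def test_fold_stratification(self, easy_weighted):
        """Each CV fold's class counts stay within 1 of exact proportion."""
        from sklearn.model_selection import StratifiedKFold

        _, weighted, labels = easy_weighted
        y = labels_to_binary(labels)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, val_idx in skf.split(np.zeros(len(y)), y):
            frac = y[val_idx].mean() * len(val_idx)
            expected = y.mean() * len(val_idx)
            assert abs(frac - expected) <= 1.0


@pytest.fixture(scope="module")
def trained(small_easy, small_easy_tc):
    counts = build_dtm(small_easy_tc)
    weighted = tfidf_transform(counts)
    sel = select_terms(weighted, small_easy_tc.labels, k=300)
    kept = [s.term for s in sel if s.selected]
    x_train = restrict_to_terms(weighted, kept)
    tc_test = preprocess_corpus(small_easy.test)
    x_test = project_onto_vocabulary(tc_test, x_train.vocabulary, counts)
    return x_train, small_easy_tc.labels, x_test, small_easy.truth


class TestFitAndClassify:

    def test_partition_contract(self, trained):
        x_train, labels, x_test, _ = trained
        res = fit_and_classify(
            x_train, labels, x_test, ClassifierSpec(Algorithm.GLMNET, {}, 1), seed=0
        )
        pos, neg = res.split_lists()
        assert sorted([res.doc_ids[i] for i in pos + neg]) == sorted(x_test.doc_ids)

    def test_probability_consistent_with_assignment(self, trained):
        x_train, labels, x_test, _ = trained
        res = fit_and_classify(
            x_train, labels, x_test, ClassifierSpec(Algorithm.GLMNET, {}, 1), seed=0
        )
        pos, neg = res.split_lists()
        if pos:
            assert min(res.probability_positive[i] for i in pos) >= 0.5
        if neg:
            assert max(res.probability_positive[i] for i in neg) < 0.5

    def test_held_out_accuracy_on_planted_signal(self, trained):
        x_train, labels, x_test, truth = trained
        res = fit_and_classify(
            x_train, labels, x_test, ClassifierSpec(Algorithm.GLMNET, {}, 1), seed=0
        )
        correct = np.mean(
            [truth[d] is lab for d, lab in zip(res.doc_ids, res.assigned)]
        )
        assert correct >= 0.9

    def test_vocabulary_mismatch_raises(self, trained):
        x_train, labels, x_test, _ = trained
        clipped = restrict_to_terms(x_test, x_test.vocabulary[:-1])
        with pytest.raises(VocabularyMismatch):
            fit_and_classify(
                x_train, labels, clipped, ClassifierSpec(Algorithm.GLMNET, {}, 1)
            )

    @pytest.mark.parametrize("algo", [Algorithm.GLMNET, Algorithm.NAIVE_BAYES])
    def test_label_swap_inverts_probabilities(self, trained, algo):
        x_train, labels, x_test, _ = trained
        spec = ClassifierSpec(algo, {}, 1)
        res = fit_and_classify(x_train, labels, x_test, spec, seed=0)
        swapped = [
            Label.NEGATIVE if lab is Label.POSITIVE else Label.POSITIVE
            for lab in labels
        ]
        res_sw = fit_and_classify(x_train, swapped, x_test, spec, seed=0)
        assert np.allclose(
            res.probability_positive, 1.0 - res_sw.probability_positive, atol=1e-6
        )

    def test_svm_scores_rank_like_margins(self, trained):
        """The logistic link on SVM margins is monotone: ranked order of
        probabilities equals ranked order of decision values."""
        from littriage.classify import _Model

        x_train, labels, x_test, _ = trained
        y = labels_to_binary(labels)
        model = _Model(ClassifierSpec(Algorithm.SVM, {}, 1), seed=0).fit(
            x_train.values, y
        )
        margins = model.est.decision_function(x_test.values)
        probs = model.predict_proba_positive(x_test.values)
        assert (np.argsort(margins) == np.argsort(probs)).all()


def test_length_only_classes_stay_at_chance():
    """Classes differing only in document length (no term signal) must not
    be separable: Tf-Idf term frequencies are length-normalised."""
    short = generate_corpus(
        GeneratorConfig(
            n_docs_per_class=50, signal_enrichment=1.0,
            doc_length_mean=100.0, seed=11,
        )
    )
    long = generate_corpus(
        GeneratorConfig(
            n_docs_per_class=50, signal_enrichment=1.0,
            doc_length_mean=200.0, seed=12,
        )
    )
    docs = [
        Document(f"s{i}", d.title, d.abstract, Label.POSITIVE)
        for i, d in enumerate(short.documents[:50])
    ] + [
        Document(f"l{i}", d.title, d.abstract, Label.NEGATIVE)
        for i, d in enumerate(long.documents[:50])
    ]
    tc = preprocess_corpus(Corpus(docs, Category.TRAIN_POS, []))
    weighted = tfidf_transform(build_dtm(tc))
    roster = [
        ClassifierSpec(Algorithm.GLMNET, {}, 1),
        ClassifierSpec(Algorithm.NAIVE_BAYES, {}, 2),
    ]
    tour = run_tournament(weighted, tc.labels, roster, folds=5, seed=0, select_k=500)
    se3 = 3 * np.sqrt(0.25 / 100)
    for r in tour.results:
        assert abs(r.mean_accuracy - 0.5) <= se3
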