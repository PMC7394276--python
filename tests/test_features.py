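"""Document-term matrices, Tf-Idf weighting, Mann-Whitney term selection."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu as scipy_mwu

from littriage.corpus_io import Label
from littriage.errors import AlreadyWeighted, EmptySample, EmptyVocabulary
from littriage.features import (
    build_dtm,
    export_dtm,
    import_dtm,
    mann_whitney_u,
    mwu_columns,
    project_onto_vocabulary,
    restrict_to_terms,
    select_terms,
    tfidf_transform,
    top_k_columns,
)
from littriage.preprocess import PreprocessConfig, TokenizedCorpus, preprocess_corpus
from littriage.corpus_io import Document
from conftest import mwu_enumeration_oracle, two_class_corpus


def tc_from_tokens(token_lists, labels=None):
    labels = labels or [Label.UNLABELED] * len(token_lists)
    docs = [
        Document(f"d{i}", "", " ".join(toks) or "x", lab)
        for i, (toks, lab) in enumerate(zip(token_lists, labels))
    ]
    return TokenizedCorpus(docs, [list(t) for t in token_lists], PreprocessConfig())


class TestBuildDtm:
    def test_direct_count(self):
        tc = tc_from_tokens([["a", "b", "a"], ["b", "c"]])
        dtm = build_dtm(tc)
        assert dtm.vocabulary == ["a", "b", "c"]
        assert dtm.toarray().tolist() == [[2, 1, 0], [0, 1, 1]]
        assert not dtm.weighted

    def test_empty_token_list_zero_row(self):
        dtm = build_dtm(tc_from_tokens([["a"], []]))
        assert dtm.toarray()[1].tolist() == [0]

    def test_column_sums_are_corpus_frequencies(self):
        rng = np.random.default_rng(0)
        token_lists = [
            list(rng.choice(list("abcde"), size=rng.integers(1, 20)))
            for _ in range(10)
        ]
        dtm = build_dtm(tc_from_tokens(token_lists))
        totals = {t: 0 for t in dtm.vocabulary}
        for toks in token_lists:
            for t in toks:
                totals[t] += 1
        assert dtm.toarray().sum(axis=0).tolist() == [
            totals[t] for t in dtm.vocabulary
        ]

    def test_all_empty_raises(self):
        with pytest.raises(EmptyVocabulary):
            build_dtm(tc_from_tokens([[], []]))


class TestTfidf:
    def test_closed_form_small(self):
        # docs: [a a b b], [a c], doc lengths 4 and 2, N=2
        dtm = build_dtm(tc_from_tokens([["a", "a", "b", "b"], ["a", "c"]]))
        w = tfidf_transform(dtm).toarray()
        # a occurs in both docs: idf = log2(2/2) = 0
        assert w[:, 0].tolist() == [0.0, 0.0]
        # b: count 2, len 4, df 1 -> (2/4) * log2(2) = 0.5
        assert w[0, 1] == pytest.approx(0.5, abs=1e-12)
        # c: count 1, len 2, df 1 -> 0.5
        assert w[1, 2] == pytest.approx(0.5, abs=1e-12)

    def test_zero_row_guarded(self):
        w = tfidf_transform(build_dtm(tc_from_tokens([["a"], []])))
        assert w.toarray()[1].tolist() == [0.0]

    def test_double_weighting_rejected(self):
        w = tfidf_transform(build_dtm(tc_from_tokens([["a", "b"], ["b"]])))
        with pytest.raises(AlreadyWeighted):
            tfidf_transform(w)

    def test_zero_pattern_preserved(self):
        rng = np.random.default_rng(1)
        token_lists = [
            list(rng.choice(list("abcdefgh"), size=rng.integers(2, 15)))
            for _ in range(8)
        ]
        dtm = build_dtm(tc_from_tokens(token_lists))
        w = tfidf_transform(dtm)
        assert (w.toarray()[dtm.toarray() == 0] == 0).all()


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 of all C(6,3) assignments

    def test_identical_samples(self):
        u, p = mann_whitney_u([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert u == pytest.approx(9 / 2)
        assert p == 1.0

    def test_empty_raises(self):
        with pytest.raises(EmptySample):
            mann_whitney_u([], [1.0])

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, 11 - n))
            vals = rng.permutation(np.arange(n + m, dtype=float) * 1.7 + 0.3)
            a, b = vals[:n], vals[n:]
            u, p = mann_whitney_u(a, b)
            u_ref, p_ref = mwu_enumeration_oracle(a, b)
            assert u == u_ref
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_asymptotic_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.integers(0, 6, size=30).astype(float)
            b = rng.integers(0, 7, size=25).astype(float)
            u, p = mann_whitney_u(a, b)
            ref = scipy_mwu(a, b, method="asymptotic", use_continuity=True)
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 2**31 - 1))
    def test_u_complementarity(self, n, m, seed):
        """U(a,b) + U(b,a) = n*m for tie-free samples."""
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(n + m, dtype=float))
        a, b = vals[:n], vals[n:]
        u_ab, _ = mann_whitney_u(a, b)
        u_ba, _ = mann_whitney_u(b, a)
        assert u_ab + u_ba == n * m


def test_mwu_columns_matches_scalar():
    """The vectorised column-wise U test reproduces the scalar asymptotic
    path on sparse-like data with heavy zero ties."""
    rng = np.random.default_rng(9)
    dense = rng.random((40, 15))
    dense[rng.random((40, 15)) < 0.7] = 0.0
    pos_mask = np.zeros(40, dtype=bool)
    pos_mask[:22] = True
    u_vec, p_vec, _ = mwu_columns(dense, pos_mask)
    for j in range(15):
        u_s, p_s = mann_whitney_u(dense[pos_mask, j], dense[~pos_mask, j])
        assert u_vec[j] == pytest.approx(u_s)
        assert p_vec[j] == pytest.approx(p_s, rel=1e-12)


def _labeled_weighted(pos_texts, neg_texts):
    corpus = two_class_corpus(pos_texts, neg_texts)
    tc = preprocess_corpus(corpus)
    dtm = build_dtm(tc)
    return tfidf_transform(dtm), tc.labels, dtm


class TestSelectTerms:
    def test_k_equals_vocab_selects_all(self):
        w, labels, _ = _labeled_weighted(
            ["alpha beta gene", "alpha gene tumor"],
            ["beta delta protein", "delta protein cells"],
        )
        sel = select_terms(w, labels, k=len(w.vocabulary))
        assert all(s.selected for s in sel)

    def test_label_swap_symmetry(self):
        w, labels, _ = _labeled_weighted(
            ["alpha beta gene mice", "alpha gene tumor mice"],
            ["beta delta protein mice", "delta protein cells mice"],
        )
        swapped = [
            Label.NEGATIVE if lab is Label.POSITIVE else Label.POSITIVE
            for lab in labels
        ]
        sel = {s.term: s for s in select_terms(w, labels, k=3)}
        sel_sw = {s.term: s for s in select_terms(w, swapped, k=3)}
        assert {t for t, s in sel.items() if s.selected} == {
            t for t, s in sel_sw.items() if s.selected
        }
        for t in sel:
            if sel[t].p_value < 1.0:
                assert sel[t].enriched_class is not sel_sw[t].enriched_class

    def test_planted_terms_recovered(self, small_easy, small_easy_tc):
        """With strong class-specific enrichment, the U-test stage keeps
        nearly all planted terms when k equals the planted count."""
        w = tfidf_transform(build_dtm(small_easy_tc))
        planted = set(small_easy.signal_terms[Label.POSITIVE]) | set(
            small_easy.signal_terms[Label.NEGATIVE]
        )
        sel = select_terms(w, small_easy_tc.labels, k=len(planted))
        chosen = {s.term for s in sel if s.selected}
        assert len(chosen & planted) / len(planted) >= 0.9

    def test_top_k_columns_agrees_with_select_terms(self, small_easy_tc):
        w = tfidf_transform(build_dtm(small_easy_tc))
        pos_mask = np.array([lab is Label.POSITIVE for lab in small_easy_tc.labels])
        cols = top_k_columns(w.values, pos_mask, 50, w.vocabulary)
        sel = select_terms(w, small_easy_tc.labels, k=50)
        assert {w.vocabulary[j] for j in cols} == {s.term for s in sel if s.selected}


class TestProjection:
    def test_training_doc_projects_to_own_row(self):
        tc = tc_from_tokens([["a", "a", "b"], ["b", "c"], ["a", "c", "c"]])
        dtm = build_dtm(tc)
        w = tfidf_transform(dtm)
        proj = project_onto_vocabulary(tc, dtm.vocabulary, dtm)
        assert np.allclose(proj.toarray(), w.toarray())

    def test_unseen_terms_give_zero_vector(self):
        train = tc_from_tokens([["a", "b"], ["b", "c"]])
        dtm = build_dtm(train)
        test = tc_from_tokens([["zz", "qq"]])
        proj = project_onto_vocabulary(test, dtm.vocabulary, dtm)
        assert proj.toarray().tolist() == [[0.0, 0.0, 0.0]]

    def test_column_order_preserved(self):
        train = tc_from_tokens([["a", "b", "c"], ["a", "c"]])
        dtm = build_dtm(train)
        sub = restrict_to_terms(dtm, ["c", "a"])
        assert sub.vocabulary == ["a", "c"]  # sorted, order deterministic
        proj = project_onto_vocabulary(train, sub.vocabulary, dtm)
        assert proj.vocabulary == ["a", "c"]


def test_mtx_round_trip(tmp_path):
    tc = tc_from_tokens([["a", "a", "b"], ["b", "c"]])
    dtm = build_dtm(tc)
    export_dtm(dtm, tmp_path / "m")
    back = import_dtm(tmp_path / "m", weighted=False)
    assert back.vocabulary == dtm.vocabulary
    assert back.doc_ids == dtm.doc_ids
    assert np.allclose(back.toarray(), dtm.toarray())
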