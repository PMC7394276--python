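"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import pytest

from littriage.corpus_io import Category, Corpus, Document, Label, Status
from littriage.preprocess import PreprocessConfig, preprocess_corpus
from littriage.synthetic import GeneratorConfig, generate_corpus, split_benchmark


def mwu_enumeration_oracle(a, b) -> tuple[float, float]:
    """Exhaustive Mann-Whitney oracle for tie-free samples.

    U = number of (a, b) pairs with a > b. The two-sided p-value is the
    fraction of all C(n+m, n) equally likely rank assignments whose U is at
    least as far from nm/2 as the observed one. Independent of the counting
    recursion used by the implementation.
    """
    a = list(a)
    b = list(b)
    n, m = len(a), len(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    center = n * m / 2.0
    positions = range(n + m)
    hits = 0
    total = 0
    for combo in itertools.combinations(positions, n):
        # ranks 0..n+m-1 assigned to group A at `combo`
        in_a = set(combo)
        u = sum(1 for i in combo for j in positions if j not in in_a and i > j)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    assert total == math.comb(n + m, n)
    return float(u_obs), hits / total


def make_corpus(texts: list[str], category=Category.TRAIN_POS,
                label=Label.POSITIVE, prefix="d") -> Corpus:
    """Corpus from raw strings (title empty), all retrieved OK."""
    docs = [
        Document(f"{prefix}{i}", "", text, label) for i, text in enumerate(texts)
    ]
    return Corpus(docs, category, [(d.doc_id, Status.OK) for d in docs])


def two_class_corpus(pos_texts: list[str], neg_texts: list[str]) -> Corpus:
    docs = [
        Document(f"p{i}", "", t, Label.POSITIVE) for i, t in enumerate(pos_texts)
    ] + [
        Document(f"n{i}", "", t, Label.NEGATIVE) for i, t in enumerate(neg_texts)
    ]
    return Corpus(docs, Category.TRAIN_POS, [(d.doc_id, Status.OK) for d in docs])


@pytest.fixture(scope="session")
def pp_config() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture(scope="session")
def small_easy():
    """Separable synthetic corpus: 100 docs/class, enrichment 10, split
    70 train / 30 test per class. Session-scoped: generated once."""
    sc = generate_corpus(GeneratorConfig(n_docs_per_class=100, seed=42))
    return split_benchmark(sc, "small-easy", 70, 30)


@pytest.fixture(scope="session")
def small_easy_tc(small_easy):
    """Tokenized combined training corpus of the small easy benchmark."""
    train = Corpus(
        small_easy.train_pos.documents + small_easy.train_neg.documents,
        Category.TRAIN_POS,
        [],
    )
    return preprocess_corpus(train)


@pytest.fixture(scope="session")
def small_null_tc():
    """No-signal corpus (enrichment 1), 60 docs/class, tokenized."""
    sc = generate_corpus(
        GeneratorConfig(n_docs_per_class=60, signal_enrichment=1.0, seed=7)
    )
    return preprocess_corpus(Corpus(sc.documents, Category.TRAIN_POS, []))
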