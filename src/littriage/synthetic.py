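"""Synthetic two-class abstract corpora with known ground truth.

Real curation corpora are proprietary to their databases, so every stage of
the pipeline is exercised on generated ones. The model: a shared background
vocabulary with Zipf-distributed frequencies (heavy-tailed, like real word
frequencies), plus two disjoint sets of class-specific "signal" terms whose
sampling weight is multiplied by a single enrichment factor in their own
class. Enrichment 1 makes the two classes distributionally identical (a
null corpus); larger values give a tunable separation knob.

Signal terms are planted at the base weight of the rank-⌈V/4⌉ background
term — mid-frequency, like realistic informative terms, neither ubiquitous
nor vanishingly rare. Document lengths are Poisson with mean 150 tokens,
matching typical abstract lengths.

The vocabulary is built from stem-stable, stopword-free pseudo-words
(alternating consonant-vowel syllables), so ground-truth terms pass through
preprocessing unchanged and stay traceable end to end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import _porter
from .corpus_io import Category, Corpus, Document, Label, Status
from .errors import InvalidConfig
from .preprocess import default_stopwords

_CONSONANTS = "bdfgklmnprtvz"
_VOWELS = "aou"
_MIN_DOC_LEN = 6


def _pseudo_words(n: int) -> list[str]:
    """First n stem-stable CVCVC pseudo-words in enumeration order."""
    stop = default_stopwords()
    out: list[str] = []
    combos = itertools.product(
        _CONSONANTS, _VOWELS, _CONSONANTS, _VOWELS, _CONSONANTS
    )
    for parts in combos:
        w = "".join(parts)
        if w in stop or _porter.stem(w) != w:
            continue
        out.append(w)
        if len(out) == n:
            return out
    raise InvalidConfig(f"cannot build a {n}-word stem-stable vocabulary")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    n_docs_per_class: int = 100
    background_vocab_size: int = 2000
    n_signal_terms_per_class: int = 50
    signal_enrichment: float = 10.0
    doc_length_mean: float = 150.0
    zipf_exponent: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_docs_per_class,
            self.background_vocab_size,
            self.n_signal_terms_per_class,
        ) < 1:
            raise InvalidConfig("all counts must be positive")
        if self.signal_enrichment < 1:
            raise InvalidConfig("signal_enrichment must be >= 1")
        if self.doc_length_mean <= 0 or self.zipf_exponent <= 0:
            raise InvalidConfig("doc_length_mean and zipf_exponent must be > 0")


@dataclass
class SyntheticCorpus:
    """Labeled documents plus the generator's ground truth."""

    documents: list[Document]
    truth: dict[str, Label]
    signal_terms: dict[Label, list[str]]
    config: GeneratorConfig

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]


def _class_probs(
    n_bg: int, n_sig: int, enrichment: float, zipf_s: float, own_first: bool
) -> np.ndarray:
    """Token distribution over [background | pos signal | neg signal]."""
    bg = np.arange(1, n_bg + 1, dtype=float) ** (-zipf_s)
    base = float(int(np.ceil(n_bg / 4))) ** (-zipf_s)
    own = np.full(n_sig, base * enrichment)
    other = np.full(n_sig, base)
    w = np.concatenate([bg, own, other] if own_first else [bg, other, own])
    return w / w.sum()


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Draw a labeled two-class corpus; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_bg = config.background_vocab_size
    n_sig = config.n_signal_terms_per_class
    words = _pseudo_words(n_bg + 2 * n_sig)
    vocab = np.array(words)
    sig_pos = words[n_bg : n_bg + n_sig]
    sig_neg = words[n_bg + n_sig :]

    documents: list[Document] = []
    truth: dict[str, Label] = {}
    for label, prefix, own_first in (
        (Label.POSITIVE, "P", True),
        (Label.NEGATIVE, "N", False),
    ):
        probs = _class_probs(
            n_bg, n_sig, config.signal_enrichment, config.zipf_exponent, own_first
        )
        lengths = np.maximum(
            rng.poisson(config.doc_length_mean, size=config.n_docs_per_class),
            _MIN_DOC_LEN,
        )
        tokens = rng.choice(len(vocab), size=int(lengths.sum()), p=probs)
        offsets = np.r_[0, np.cumsum(lengths)]
        for i in range(config.n_docs_per_class):
            toks = vocab[tokens[offsets[i] : offsets[i + 1]]]
            doc_id = f"{prefix}{i + 1:05d}"
            doc = Document(
                doc_id,
                title=" ".join(toks[:3]),
                abstract=" ".join(toks[3:]),
                label=label,
            )
            documents.append(doc)
            truth[doc_id] = label
    return SyntheticCorpus(
        documents,
        truth,
        {Label.POSITIVE: list(sig_pos), Label.NEGATIVE: list(sig_neg)},
        config,
    )


def _as_corpus(docs: list[Document], category: Category) -> Corpus:
    return Corpus(
        list(docs), category, [(d.doc_id, Status.OK) for d in docs]
    )


@dataclass
class Benchmark:
    """A train/test split of one synthetic corpus, pipeline-ready."""

    name: str
    train_pos: Corpus
    train_neg: Corpus
    test: Corpus  # labels stripped to UNLABELED
    truth: dict[str, Label]
    signal_terms: dict[Label, list[str]]
    config: GeneratorConfig


def split_benchmark(
    sc: SyntheticCorpus, name: str, n_train_per_class: int, n_test_per_class: int
) -> Benchmark:
    """Deterministic balanced split: first documents of each class train,
    the next block is the held-out test set (documents are i.i.d.)."""
    per_class = sc.config.n_docs_per_class
    if n_train_per_class + n_test_per_class > per_class:
        raise InvalidConfig(
            f"split {n_train_per_class}+{n_test_per_class} exceeds "
            f"{per_class} documents per class"
        )
    by_label: dict[Label, list[Document]] = {Label.POSITIVE: [], Label.NEGATIVE: []}
    for d in sc.documents:
        by_label[d.label].append(d)
    train_pos = by_label[Label.POSITIVE][:n_train_per_class]
    train_neg = by_label[Label.NEGATIVE][:n_train_per_class]
    test_docs = [
        Document(d.doc_id, d.title, d.abstract, Label.UNLABELED)
        for lab in (Label.POSITIVE, Label.NEGATIVE)
        for d in by_label[lab][n_train_per_class : n_train_per_class + n_test_per_class]
    ]
    return Benchmark(
        name,
        _as_corpus(train_pos, Category.TRAIN_POS),
        _as_corpus(train_neg, Category.TRAIN_NEG),
        _as_corpus(test_docs, Category.CLASSIFY),
        dict(sc.truth),
        dict(sc.signal_terms),
        sc.config,
    )


BENCHMARK_ENRICHMENT = {"easy": 10.0, "hard": 2.0, "null": 1.0}


def make_benchmark_suite(
    seed: int,
    n_train_per_class: int = 750,
    n_test_per_class: int = 250,
) -> dict[str, Benchmark]:
    """Three fixed-recipe corpora — easy (enrichment 10), hard (2), null (1)
    — each 2000 documents split 1500 train / 500 test, balanced."""
    suite = {}
    for i, (name, enrichment) in enumerate(BENCHMARK_ENRICHMENT.items()):
        config = GeneratorConfig(
            n_docs_per_class=n_train_per_class + n_test_per_class,
            signal_enrichment=enrichment,
            seed=seed * 4 + i,
        )
        sc = generate_corpus(config)
        suite[name] = split_benchmark(sc, name, n_train_per_class, n_test_per_class)
    return suite
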