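"""Text normalisation and tokenisation.

The pipeline applies five operations to each abstract: lowercase folding,
punctuation removal, whitespace tokenisation, stopword removal, and Porter
stemming — with one domain-specific rule: standalone numbers are dropped but
tokens mixing letters and digits (gene names like p53, CD8) are kept intact.

Punctuation handling is configurable: ``DELETE`` removes punctuation in
place (hyphenated words concatenate, mirroring classic text-mining toolkits);
``SPACE`` replaces it with a space so compound parts stay separate tokens.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from . import _porter
from .corpus_io import Corpus, Document
from .errors import EmptyCorpus

logger = logging.getLogger(__name__)


class Stemmer(Enum):
    PORTER = "PORTER"
    NONE = "NONE"


class PunctuationMode(Enum):
    DELETE = "DELETE"
    SPACE = "SPACE"


def default_stopwords() -> frozenset[str]:
    """The built-in English stopword list (scikit-learn's frozen list)."""
    from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

    return frozenset(ENGLISH_STOP_WORDS)


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a stopword lexicon: one word per line, '#' comments allowed."""
    words = set()
    for line in Path(path).read_text().splitlines():
        w = line.split("#", 1)[0].strip().lower()
        if w:
            words.add(w)
    return frozenset(words)


@dataclass(frozen=True)
class PreprocessConfig:
    """Normalisation settings, recorded into run provenance."""

    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    stopword_list_name: str = "sklearn-english"
    stemmer: Stemmer = Stemmer.PORTER
    punctuation_mode: PunctuationMode = PunctuationMode.DELETE
    keep_alphanumeric: bool = True
    include_title: bool = True

    def __post_init__(self) -> None:
        if any(w != w.lower() for w in self.stopwords):
            raise ValueError("stopword list entries must be lowercase")

    def provenance(self) -> dict:
        return {
            "stopword_list": self.stopword_list_name,
            "n_stopwords": len(self.stopwords),
            "stemmer": self.stemmer.value,
            "punctuation_mode": self.punctuation_mode.value,
            "keep_alphanumeric": self.keep_alphanumeric,
            "include_title": self.include_title,
        }


@dataclass
class TokenizedCorpus:
    """A corpus plus its per-document token sequences and provenance."""

    documents: list[Document]
    tokens: list[list[str]]
    config: PreprocessConfig

    def __post_init__(self) -> None:
        if len(self.documents) != len(self.tokens):
            raise ValueError("documents and token lists must align")

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    @property
    def labels(self) -> list:
        return [d.label for d in self.documents]


_PURE_NUMBER = re.compile(r"^[0-9]+$")
# "punctuation" = anything that is neither a letter, a digit, nor whitespace
_NOT_WORD_WS = re.compile(r"[^\w\s]|_", re.UNICODE)


def normalize_and_tokenize(raw: str, config: PreprocessConfig) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace, drop pure numbers."""
    text = unicodedata.normalize("NFKC", raw).lower()
    repl = "" if config.punctuation_mode is PunctuationMode.DELETE else " "
    text = _NOT_WORD_WS.sub(repl, text)
    tokens = text.split()
    return [t for t in tokens if not _PURE_NUMBER.match(t)]


def filter_and_stem(tokens: list[str], config: PreprocessConfig) -> list[str]:
    """Remove stopwords (exact match), then stem; order preserved."""
    kept = (t for t in tokens if t not in config.stopwords)
    if config.stemmer is Stemmer.PORTER:
        return [_porter.stem(t) for t in kept]
    return list(kept)


def preprocess_text(raw: str, config: PreprocessConfig) -> list[str]:
    """Full per-document preprocessing: normalise → filter → stem."""
    return filter_and_stem(normalize_and_tokenize(raw, config), config)


def preprocess_corpus(corpus: Corpus, config: PreprocessConfig | None = None) -> TokenizedCorpus:
    """Tokenise every document of a corpus.

    Documents that end up with zero tokens are retained (empty token list)
    and logged, so downstream accounting never silently drops a document.
    """
    if config is None:
        config = PreprocessConfig()
    if len(corpus) == 0:
        raise EmptyCorpus("cannot preprocess an empty corpus")
    token_lists = []
    for doc in corpus.documents:
        toks = preprocess_text(doc.text(config.include_title), config)
        if not toks:
            logger.warning("document %s yielded zero tokens", doc.doc_id)
        token_lists.append(toks)
    return TokenizedCorpus(list(corpus.documents), token_lists, config)


def retokenize(tc: TokenizedCorpus) -> TokenizedCorpus:
    """Re-run preprocessing on the space-joined token output (a fixed point)."""
    token_lists = [preprocess_text(" ".join(toks), tc.config) for toks in tc.tokens]
    return replace_tokens(tc, token_lists)


def replace_tokens(tc: TokenizedCorpus, token_lists: list[list[str]]) -> TokenizedCorpus:
    return TokenizedCorpus(list(tc.documents), token_lists, tc.config)
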