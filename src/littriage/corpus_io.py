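"""Corpus ingestion: PubMed ID lists, E-utilities retrieval, local files.

Abstracts can come from NCBI's efetch endpoint (live) or from any object
implementing the :class:`Transport` protocol — tests and offline runs inject
a fixture backend, so nothing in the package requires network access.
Retrieved records are normalised to :class:`Document`; every requested ID is
accounted for in the corpus retrieval log with one of the statuses
``OK``, ``NO_ABSTRACT``, ``NOT_FOUND``.
"""

from __future__ import annotations

import logging
import re
import time
import urllib.parse
import urllib.request
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import pandas as pd

from .errors import (
    AllRecordsFailed,
    EmptyCorpus,
    EmptyInput,
    MalformedID,
    MissingColumn,
    NetworkError,
)

logger = logging.getLogger(__name__)

EFETCH_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
BATCH_SIZE = 200          # NCBI etiquette: bounded request size
REQUEST_DELAY_S = 0.34    # ≤3 requests/s without an API key
MAX_RETRIES = 3


class Label(Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNLABELED = "UNLABELED"


class Category(Enum):
    TRAIN_POS = "TRAIN_POS"
    TRAIN_NEG = "TRAIN_NEG"
    CLASSIFY = "CLASSIFY"


class Status(Enum):
    OK = "OK"
    NO_ABSTRACT = "NO_ABSTRACT"
    NOT_FOUND = "NOT_FOUND"


@dataclass(frozen=True)
class Document:
    """One abstract record."""

    doc_id: str
    title: str
    abstract: str
    label: Label = Label.UNLABELED

    def text(self, include_title: bool = True) -> str:
        """Text fed to preprocessing: title + abstract by default."""
        if include_title and self.title:
            return f"{self.title} {self.abstract}"
        return self.abstract


@dataclass
class Corpus:
    """Ordered documents of one category plus per-ID retrieval accounting."""

    documents: list[Document]
    category: Category
    retrieval_log: list[tuple[str, Status]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate doc_id in corpus")

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]


_CATEGORY_LABEL = {
    Category.TRAIN_POS: Label.POSITIVE,
    Category.TRAIN_NEG: Label.NEGATIVE,
    Category.CLASSIFY: Label.UNLABELED,
}


def parse_pmid_list(text: str) -> list[str]:
    """Parse a newline- or comma-delimited list of PubMed IDs.

    Duplicates are dropped (order-preserving, warning logged); non-numeric
    tokens are skipped with a warning. Raises :class:`MalformedID` if every
    token is malformed and :class:`EmptyInput` if nothing remains.
    """
    tokens = [t.strip() for t in re.split(r"[,\n\r]+", text) if t.strip()]
    if not tokens:
        raise EmptyInput("no PubMed ID found in input")
    valid = [t for t in tokens if t.isdigit()]
    if not valid:
        raise MalformedID(f"all {len(tokens)} tokens are non-numeric")
    for bad in (t for t in tokens if not t.isdigit()):
        logger.warning("skipping malformed ID %r", bad)
    seen: set[str] = set()
    out: list[str] = []
    for t in valid:
        if t in seen:
            logger.warning("duplicate ID %s dropped", t)
        else:
            seen.add(t)
            out.append(t)
    return out


class Transport(Protocol):
    """Retrieval backend: one batch of IDs in, raw PubMed XML out."""

    def fetch(self, ids: Sequence[str]) -> str:  # pragma: no cover - protocol
        ...


class EntrezTransport:
    """Live NCBI efetch backend (db=pubmed, XML), with bounded retries."""

    def __init__(self, email: str | None = None, api_key: str | None = None):
        self.email = email
        self.api_key = api_key
        self._last_request = 0.0

    def fetch(self, ids: Sequence[str]) -> str:
        params = {"db": "pubmed", "id": ",".join(ids), "retmode": "xml"}
        if self.email:
            params["email"] = self.email
        if self.api_key:
            params["api_key"] = self.api_key
        data = urllib.parse.urlencode(params).encode()
        wait = REQUEST_DELAY_S - (time.monotonic() - self._last_request)
        if wait > 0:
            time.sleep(wait)
        last_err: Exception | None = None
        for attempt in range(MAX_RETRIES):
            try:
                self._last_request = time.monotonic()
                with urllib.request.urlopen(EFETCH_URL, data=data, timeout=60) as r:
                    return r.read().decode("utf-8", errors="replace")
            except Exception as exc:  # noqa: BLE001 - retried, then wrapped
                last_err = exc
                time.sleep(2.0 * (attempt + 1))
        raise NetworkError(f"efetch failed after {MAX_RETRIES} retries: {last_err}")


class FixtureTransport:
    """In-memory backend mapping doc_id -> (title, abstract-or-None).

    Emits well-formed PubmedArticleSet XML so the real parser is exercised.
    Unknown IDs are simply absent from the response (as efetch behaves).
    """

    def __init__(self, records: dict[str, tuple[str, str | None]]):
        self.records = dict(records)
        self.calls: list[list[str]] = []

    def fetch(self, ids: Sequence[str]) -> str:
        self.calls.append(list(ids))
        parts = ["<?xml version='1.0'?><PubmedArticleSet>"]
        for pmid in ids:
            if pmid not in self.records:
                continue
            title, abstract = self.records[pmid]
            abs_xml = (
                f"<Abstract><AbstractText>{abstract}</AbstractText></Abstract>"
                if abstract
                else ""
            )
            parts.append(
                "<PubmedArticle><MedlineCitation>"
                f"<PMID>{pmid}</PMID><Article>"
                f"<ArticleTitle>{title}</ArticleTitle>{abs_xml}"
                "</Article></MedlineCitation></PubmedArticle>"
            )
        parts.append("</PubmedArticleSet>")
        return "".join(parts)


def parse_pubmed_xml(xml_text: str) -> dict[str, tuple[str, str]]:
    """Extract {pmid: (title, abstract)} from PubmedArticleSet XML.

    Labeled abstract sections are concatenated in document order; records
    without any abstract text map to an empty abstract string.
    """
    root = ET.fromstring(xml_text)
    out: dict[str, tuple[str, str]] = {}
    for art in root.iter("PubmedArticle"):
        pmid_el = art.find(".//MedlineCitation/PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            continue
        pmid = pmid_el.text.strip()
        title_el = art.find(".//Article/ArticleTitle")
        title = "".join((title_el.itertext())) if title_el is not None else ""
        sections = [
            " ".join(t.strip() for t in el.itertext() if t.strip())
            for el in art.findall(".//Article/Abstract/AbstractText")
        ]
        abstract = " ".join(s for s in sections if s)
        out[pmid] = (title.strip(), abstract.strip())
    return out


def fetch_abstracts(
    ids: Sequence[str],
    category: Category,
    transport: Transport,
) -> Corpus:
    """Retrieve abstracts in batches of ≤200 IDs and assemble a corpus.

    Records lacking an abstract are excluded (logged ``NO_ABSTRACT``); IDs
    absent from the response are logged ``NOT_FOUND``. Raises
    :class:`AllRecordsFailed` if no document survives.
    """
    label = _CATEGORY_LABEL[category]
    documents: list[Document] = []
    log: list[tuple[str, Status]] = []
    for start in range(0, len(ids), BATCH_SIZE):
        batch = list(ids[start : start + BATCH_SIZE])
        records = parse_pubmed_xml(transport.fetch(batch))
        for pmid in batch:
            if pmid not in records:
                log.append((pmid, Status.NOT_FOUND))
                continue
            title, abstract = records[pmid]
            if not abstract:
                logger.warning("PMID %s has no abstract; skipped", pmid)
                log.append((pmid, Status.NO_ABSTRACT))
                continue
            documents.append(Document(pmid, title, abstract, label))
            log.append((pmid, Status.OK))
    if not documents:
        raise AllRecordsFailed(
            f"none of the {len(ids)} requested records yielded an abstract"
        )
    return Corpus(documents, category, log)


def read_corpus_file(path: str | Path, category: Category) -> Corpus:
    """Read a local delimited corpus (columns: id, title, abstract).

    Delimiter is sniffed from the extension (.tsv → tab, else comma).
    Rows with an empty abstract are skipped and logged ``NO_ABSTRACT``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"id", "title", "abstract"} - set(df.columns)
    if missing:
        raise MissingColumn(f"{path}: missing column(s) {sorted(missing)}")
    label = _CATEGORY_LABEL[category]
    documents: list[Document] = []
    log: list[tuple[str, Status]] = []
    for row in df.itertuples(index=False):
        doc_id = str(row.id).strip()
        abstract = str(row.abstract).strip()
        if not abstract:
            logger.warning("row %s has empty abstract; skipped", doc_id)
            log.append((doc_id, Status.NO_ABSTRACT))
            continue
        documents.append(Document(doc_id, str(row.title).strip(), abstract, label))
        log.append((doc_id, Status.OK))
    if not documents:
        raise EmptyCorpus(f"{path}: no row with a non-empty abstract")
    return Corpus(documents, category, log)


def write_corpus_file(corpus: Corpus | Iterable[Document], path: str | Path) -> None:
    """Write documents as the CSV corpus format read by :func:`read_corpus_file`."""
    docs = corpus.documents if isinstance(corpus, Corpus) else list(corpus)
    df = pd.DataFrame(
        {
            "id": [d.doc_id for d in docs],
            "title": [d.title for d in docs],
            "abstract": [d.abstract for d in docs],
        }
    )
    df.to_csv(path, index=False)
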