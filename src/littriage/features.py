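"""Document-term matrices, Tf-Idf weighting, and Mann-Whitney term selection.

The feature pipeline is: raw token counts → Tf-Idf weights → per-term
two-sample Mann-Whitney U between the two training classes → keep the k
most differential terms. The Tf-Idf variant is the classic length-normalised
form

    w(t, d) = (count(t, d) / len(d)) * log2(N / df(t)),

so a term occurring in every document carries zero weight. Unlabeled
documents are projected onto the *training* vocabulary and weighted with
training idf values, keeping train and test features commensurable.

The U statistic follows the rank-sum convention U = R_a - n_a(n_a+1)/2
(number of (a, b) pairs with a > b, ties counting one half). P-values are
exact (distribution by counting recursion) for tie-free samples with
n_a + n_b <= 12 and otherwise use the normal approximation with midrank tie
correction and continuity correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from .corpus_io import Label
from .errors import (
    AlreadyWeighted,
    EmptySample,
    EmptyVocabulary,
    VocabularyMismatch,
)
from .preprocess import TokenizedCorpus

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # exact U distribution up to this combined sample size


@dataclass
class DocumentTermMatrix:
    """Documents × terms matrix (raw counts or Tf-Idf weights).

    ``values`` is CSR sparse; the vocabulary is lexicographically sorted so
    column order is deterministic. ``doc_lengths`` holds the total token
    count per document of the *source* corpus (needed for term-frequency
    normalisation even after projection onto a smaller vocabulary).
    """

    doc_ids: list[str]
    vocabulary: list[str]
    values: sp.csr_matrix
    weighted: bool
    doc_lengths: np.ndarray  # total tokens per document, source corpus

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.doc_ids), len(self.vocabulary)):
            raise ValueError("matrix shape does not match ids/vocabulary")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("matrix values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def document_frequencies(self) -> np.ndarray:
        """Number of documents each term occurs in (df)."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()


def build_dtm(tc: TokenizedCorpus) -> DocumentTermMatrix:
    """Count tokens per document over the corpus-wide sorted vocabulary."""
    vocab = sorted({t for toks in tc.tokens for t in toks})
    if not vocab:
        raise EmptyVocabulary("all documents have empty token lists")
    col = {t: j for j, t in enumerate(vocab)}
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for toks in tc.tokens:
        counts: dict[int, int] = {}
        for t in toks:
            counts[col[t]] = counts.get(col[t], 0) + 1
        for j in sorted(counts):
            indices.append(j)
            data.append(counts[j])
        indptr.append(len(indices))
    values = sp.csr_matrix(
        (np.array(data, dtype=np.int64), indices, indptr),
        shape=(len(tc), len(vocab)),
    )
    lengths = np.array([len(toks) for toks in tc.tokens], dtype=np.int64)
    return DocumentTermMatrix(tc.doc_ids, vocab, values, False, lengths)


def _weight(
    counts: sp.csr_matrix,
    doc_lengths: np.ndarray,
    idf: np.ndarray,
) -> sp.csr_matrix:
    lengths = doc_lengths.astype(float)
    inv_len = np.divide(1.0, lengths, out=np.zeros_like(lengths), where=lengths > 0)
    tf = sp.diags(inv_len) @ counts.astype(float)
    return (tf @ sp.diags(idf)).tocsr()


def tfidf_transform(dtm: DocumentTermMatrix) -> DocumentTermMatrix:
    """Apply w(t,d) = (count/len(d)) * log2(N / df(t)).

    Zero-length documents stay all-zero rows; terms present in every
    document get weight 0 everywhere (log2(1) = 0).
    """
    if dtm.weighted:
        raise AlreadyWeighted("matrix is already Tf-Idf weighted")
    n_docs = len(dtm.doc_ids)
    df = dtm.document_frequencies()
    idf = np.where(df > 0, np.log2(n_docs / np.maximum(df, 1)), 0.0)
    values = _weight(dtm.values, dtm.doc_lengths, idf)
    values.eliminate_zeros()
    return DocumentTermMatrix(
        list(dtm.doc_ids), list(dtm.vocabulary), values, True, dtm.doc_lengths.copy()
    )


# --- Mann-Whitney U ----------------------------------------------------------


@lru_cache(maxsize=None)
def _u_count(u: int, n: int, m: int) -> int:
    """Number of rank arrangements of n-vs-m samples with U statistic u."""
    if u < 0:
        return 0
    if n == 0 or m == 0:
        return 1 if u == 0 else 0
    return _u_count(u - m, n - 1, m) + _u_count(u, n, m - 1)


def _u_cdf(u: int, n: int, m: int) -> float:
    total = math.comb(n + m, n)
    return sum(_u_count(k, n, m) for k in range(u + 1)) / total


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U_a, p).

    U is for sample ``a`` (small U means ``a`` tends to rank lower). Exact
    p-value by the counting recursion when the combined tie-free sample has
    at most 12 observations; normal approximation with midrank tie
    correction and 0.5 continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise EmptySample("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)  # midranks
    r_a = ranks[:n].sum()
    u = r_a - n * (n + 1) / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and n + m <= EXACT_MAX_N:
        u_int = int(round(u))
        p_le = _u_cdf(u_int, n, m)
        p_ge = _u_cdf(n * m - u_int, n, m)  # symmetry: P(U >= u) = P(U <= nm-u)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u), p

    nm = n * m
    mean = nm / 2.0
    tot = n + m
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (tot * (tot - 1))
    var = nm / 12.0 * (tot + 1 - tie_term)
    if var <= 0:
        return float(u), 1.0
    diff = u - mean
    # continuity correction toward the mean
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return float(u), float(p)


def mwu_columns(
    dense: np.ndarray, pos_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise Mann-Whitney U (asymptotic path) for a docs × terms array.

    Returns (U, p, mean-rank difference) per column; identical formulas to
    the scalar :func:`mann_whitney_u` asymptotic branch, vectorised over
    terms. The tie term exploits sparsity: the zero block is counted in
    closed form and only non-zero values are grouped.
    """
    n, n_terms = dense.shape
    n_pos = int(pos_mask.sum())
    n_neg = n - n_pos
    ranks = rankdata(dense, axis=0)
    r_pos = ranks[pos_mask].sum(axis=0)
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    tie = np.empty(n_terms)
    for j in range(n_terms):
        col = dense[:, j]
        nz = col[col != 0.0]
        c0 = n - nz.size
        t = c0**3 - c0
        if nz.size:
            cnt = np.unique(nz, return_counts=True)[1]
            t += int((cnt**3 - cnt).sum())
        tie[j] = t
    var = n_pos * n_neg / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    diff = u - n_pos * n_neg / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(diff != 0, (diff - 0.5 * np.sign(diff)) / np.sqrt(var), 0.0)
    p = np.where(var > 0, np.minimum(1.0, 2.0 * norm.sf(np.abs(np.nan_to_num(z)))), 1.0)
    mean_diff = ranks[pos_mask].mean(axis=0) - ranks[~pos_mask].mean(axis=0)
    return u, p, mean_diff


def top_k_columns(
    values: sp.csr_matrix | np.ndarray,
    pos_mask: np.ndarray,
    k: int,
    terms: list[str] | None = None,
) -> np.ndarray:
    """Column indices of the k most class-differential terms.

    Ordering: ascending p, then descending |mean-rank difference|, then
    term (or column index) — the same rule as :func:`select_terms`.
    Returned indices are sorted so column order is preserved.
    """
    dense = values.toarray() if sp.issparse(values) else np.asarray(values)
    _, p, mean_diff = mwu_columns(dense, pos_mask)
    names = terms if terms is not None else list(range(dense.shape[1]))
    order = sorted(
        range(dense.shape[1]), key=lambda j: (p[j], -abs(mean_diff[j]), names[j])
    )
    return np.sort(np.array(order[: min(k, dense.shape[1])], dtype=int))


@dataclass(frozen=True)
class TermSelection:
    """Per-term differential statistics between the two training classes."""

    term: str
    u_statistic: float
    p_value: float
    enriched_class: Label
    rank_sum_diff: float
    selected: bool


def select_terms(
    wdtm: DocumentTermMatrix,
    labels: list[Label],
    k: int,
) -> list[TermSelection]:
    """Rank terms by two-sample Mann-Whitney p-value and select the top k.

    Per term, the Tf-Idf weight vectors of the two classes are compared;
    terms are ordered by ascending p, ties broken by descending absolute
    mean-rank difference, then lexicographically. ``enriched_class`` is the
    class with the higher mean rank.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels_arr = np.array([lab.value for lab in labels])
    pos_mask = labels_arr == Label.POSITIVE.value
    neg_mask = labels_arr == Label.NEGATIVE.value
    if not pos_mask.any() or not neg_mask.any():
        raise EmptySample("both classes must be present")
    n_pos, n_neg = int(pos_mask.sum()), int(neg_mask.sum())

    dense = wdtm.toarray()
    n_docs, n_terms = dense.shape
    if k > n_terms:
        logger.warning("k=%d exceeds vocabulary size %d; selecting all", k, n_terms)

    results = []
    if n_docs <= EXACT_MAX_N:
        # tiny corpora: scalar path so tie-free columns get exact p-values
        for j, term in enumerate(wdtm.vocabulary):
            col = dense[:, j]
            u, p = mann_whitney_u(col[pos_mask], col[neg_mask])
            ranks = rankdata(col)
            diff = ranks[pos_mask].mean() - ranks[neg_mask].mean()
            enriched = Label.POSITIVE if diff >= 0 else Label.NEGATIVE
            results.append((term, u, p, enriched, diff))
    else:
        u_all, p_all, diff_all = mwu_columns(dense, pos_mask)
        for j, term in enumerate(wdtm.vocabulary):
            enriched = Label.POSITIVE if diff_all[j] >= 0 else Label.NEGATIVE
            results.append((term, u_all[j], p_all[j], enriched, diff_all[j]))

    order = sorted(results, key=lambda r: (r[2], -abs(r[4]), r[0]))
    chosen = {r[0] for r in order[: min(k, n_terms)]}
    return [
        TermSelection(term, u, p, enriched, diff, term in chosen)
        for term, u, p, enriched, diff in results
    ]


def restrict_to_terms(
    dtm: DocumentTermMatrix, terms: list[str]
) -> DocumentTermMatrix:
    """Column-subset a matrix to the given terms (kept in sorted order)."""
    keep = sorted(set(terms) & set(dtm.vocabulary))
    col = {t: j for j, t in enumerate(dtm.vocabulary)}
    idx = [col[t] for t in keep]
    return DocumentTermMatrix(
        list(dtm.doc_ids),
        keep,
        dtm.values[:, idx].tocsr(),
        dtm.weighted,
        dtm.doc_lengths.copy(),
    )


def project_onto_vocabulary(
    tc: TokenizedCorpus,
    vocabulary: list[str],
    idf_source: DocumentTermMatrix,
) -> DocumentTermMatrix:
    """Count test documents over a training vocabulary and weight with
    the training corpus's idf (df and N from ``idf_source``, which must be
    the raw-count training matrix).

    Documents with zero in-vocabulary tokens become all-zero rows (flagged
    via a warning). Document lengths are the *full* token counts, so the
    term-frequency normalisation matches the training convention.
    """
    if idf_source.weighted:
        raise AlreadyWeighted("idf_source must be the raw-count training DTM")
    src_col = {t: j for j, t in enumerate(idf_source.vocabulary)}
    missing = [t for t in vocabulary if t not in src_col]
    if missing:
        raise VocabularyMismatch(
            f"{len(missing)} terms absent from idf_source vocabulary"
        )
    n_train = len(idf_source.doc_ids)
    df_all = idf_source.document_frequencies()
    idf = np.array(
        [
            np.log2(n_train / df_all[src_col[t]]) if df_all[src_col[t]] > 0 else 0.0
            for t in vocabulary
        ]
    )
    col = {t: j for j, t in enumerate(vocabulary)}
    rows, cols, data = [], [], []
    for i, toks in enumerate(tc.tokens):
        counts: dict[int, int] = {}
        for t in toks:
            j = col.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        if not counts and toks:
            logger.warning(
                "document %s has no in-vocabulary tokens", tc.doc_ids[i]
            )
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            data.append(c)
    counts_mat = sp.csr_matrix(
        (np.array(data, dtype=float), (rows, cols)),
        shape=(len(tc), len(vocabulary)),
    )
    lengths = np.array([len(toks) for toks in tc.tokens], dtype=np.int64)
    values = _weight(counts_mat, lengths, idf)
    values.eliminate_zeros()
    return DocumentTermMatrix(tc.doc_ids, list(vocabulary), values, True, lengths)


# --- MatrixMarket export/import ---------------------------------------------


def export_dtm(dtm: DocumentTermMatrix, prefix: str | Path) -> None:
    """Write <prefix>.mtx plus <prefix>.terms.txt and <prefix>.docs.txt."""
    prefix = Path(prefix)
    from scipy.io import mmwrite

    mmwrite(str(prefix.with_suffix(".mtx")), dtm.values)
    prefix.with_suffix(".terms.txt").write_text("\n".join(dtm.vocabulary) + "\n")
    prefix.with_suffix(".docs.txt").write_text("\n".join(dtm.doc_ids) + "\n")


def import_dtm(prefix: str | Path, weighted: bool) -> DocumentTermMatrix:
    """Read a matrix written by :func:`export_dtm`.

    Document lengths are reconstructed as row sums, which is exact for raw
    count matrices and a placeholder for weighted ones.
    """
    prefix = Path(prefix)
    from scipy.io import mmread

    values = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
    terms = prefix.with_suffix(".terms.txt").read_text().split()
    docs = prefix.with_suffix(".docs.txt").read_text().split()
    lengths = np.asarray(values.sum(axis=1)).ravel().astype(np.int64 if not weighted else np.int64)
    return DocumentTermMatrix(docs, terms, values, weighted, lengths)
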