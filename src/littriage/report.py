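"""Result artifacts: ranked lists, differential term signature, PCA coordinates.

Three outputs characterise a run: (1) two CSV lists of classified documents
ranked by descending class confidence, (2) the 50-term signature — the 25
terms most enriched in each training class by mean Tf-Idf difference, the
data behind the original word-cloud display — and (3) two-dimensional PCA
coordinates of all documents for class-separation visualisation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .classify import ClassificationResult, labels_to_binary
from .corpus_io import Document, Label
from .errors import IOFailure, VocabularyMismatch
from .features import DocumentTermMatrix

logger = logging.getLogger(__name__)


@dataclass
class TermSignature:
    """Most class-differential terms with their mean-difference scores.

    ``positive_terms``/``negative_terms`` are (term, score) pairs where
    score is the mean Tf-Idf difference (positive class minus negative);
    signs are positive for the positive list and negative for the negative
    list by construction.
    """

    positive_terms: list[tuple[str, float]]
    negative_terms: list[tuple[str, float]]

    @property
    def terms(self) -> list[str]:
        return [t for t, _ in self.positive_terms] + [
            t for t, _ in self.negative_terms
        ]


def term_signature(
    wdtm: DocumentTermMatrix,
    labels: list[Label],
    n_per_class: int = 25,
) -> TermSignature:
    """Top ``n_per_class`` terms per class by mean Tf-Idf difference.

    Ties are broken lexicographically. If the vocabulary is too small to
    fill both lists a warning is logged and fewer terms are returned;
    the two lists are always disjoint.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    y = labels_to_binary(labels)
    dense = wdtm.toarray()
    mean_pos = dense[y == 1].mean(axis=0)
    mean_neg = dense[y == 0].mean(axis=0)
    diff = mean_pos - mean_neg

    order = sorted(
        range(len(wdtm.vocabulary)),
        key=lambda j: (-diff[j], wdtm.vocabulary[j]),
    )
    n_half = len(order) // 2
    if n_per_class > n_half:
        logger.warning(
            "vocabulary of %d terms cannot fill 2x%d signature slots",
            len(order), n_per_class,
        )
    take = min(n_per_class, n_half)
    pos_idx = [j for j in order if diff[j] > 0][:take]
    neg_order = sorted(
        range(len(wdtm.vocabulary)),
        key=lambda j: (diff[j], wdtm.vocabulary[j]),
    )
    neg_idx = [j for j in neg_order if diff[j] < 0][:take]
    vocab = wdtm.vocabulary
    return TermSignature(
        [(vocab[j], float(diff[j])) for j in pos_idx],
        [(vocab[j], float(diff[j])) for j in neg_idx],
    )


class Role:
    TRAIN_POS = "TRAIN_POS"
    TRAIN_NEG = "TRAIN_NEG"
    CLASSIFIED_POS = "CLASSIFIED_POS"
    CLASSIFIED_NEG = "CLASSIFIED_NEG"


@dataclass
class ProjectionResult:
    """First two principal-component scores per document, with roles."""

    doc_ids: list[str]
    pc1: np.ndarray
    pc2: np.ndarray
    roles: list[str]
    explained_variance_ratio: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "doc_id": self.doc_ids,
                "pc1": self.pc1,
                "pc2": self.pc2,
                "role": self.roles,
            }
        )


def pca_projection(
    wdtm_train: DocumentTermMatrix,
    wdtm_test: DocumentTermMatrix,
    train_labels: list[Label],
    assignments: ClassificationResult | None = None,
    fit_on: str = "combined",
) -> ProjectionResult:
    """PCA of the stacked, column-mean-centred Tf-Idf matrix.

    ``fit_on='combined'`` (default) fits on training + test documents
    together; ``'train'`` fits on training rows and projects the rest.
    Component signs are fixed by forcing each component's
    largest-magnitude loading positive, so coordinates are reproducible.
    """
    if wdtm_train.vocabulary != wdtm_test.vocabulary:
        raise VocabularyMismatch("train and test matrices must share vocabulary")
    x_train = wdtm_train.toarray()
    x_test = wdtm_test.toarray()
    stacked = np.vstack([x_train, x_test])

    pca = PCA(n_components=2, svd_solver="full", random_state=0)
    if fit_on == "train":
        pca.fit(x_train)
        coords = pca.transform(stacked)  # centred on the training fit mean
    else:
        coords = pca.fit_transform(stacked)

    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(2):
        comp = pca.components_[c]
        if comp[np.argmax(np.abs(comp))] < 0:
            pca.components_[c] = -comp
            coords[:, c] = -coords[:, c]

    y = labels_to_binary(train_labels)
    roles = [Role.TRAIN_POS if v == 1 else Role.TRAIN_NEG for v in y]
    if assignments is not None:
        assigned = {
            d: lab for d, lab in zip(assignments.doc_ids, assignments.assigned)
        }
        roles += [
            Role.CLASSIFIED_POS
            if assigned.get(d) is Label.POSITIVE
            else Role.CLASSIFIED_NEG
            for d in wdtm_test.doc_ids
        ]
    else:
        roles += [Role.CLASSIFIED_NEG] * len(wdtm_test.doc_ids)

    evr = pca.explained_variance_ratio_
    return ProjectionResult(
        list(wdtm_train.doc_ids) + list(wdtm_test.doc_ids),
        coords[:, 0],
        coords[:, 1],
        roles,
        (float(evr[0]), float(evr[1])),
    )


def write_outputs(
    result: ClassificationResult,
    signature: TermSignature,
    projection: ProjectionResult,
    out_dir: str | Path,
    documents: dict[str, Document] | None = None,
    run_log: dict | None = None,
) -> dict[str, str]:
    """Write all run artifacts to ``out_dir`` and return a file manifest.

    Files: positive.csv / negative.csv (rank, doc_id, title, probability of
    the assigned class's direction), metrics.json (tournament results),
    signature.csv, projection.csv, run_log.json.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, str] = {}
        documents = documents or {}
        pos, neg = result.split_lists()
        for name, idx_list in (("positive", pos), ("negative", neg)):
            rows = []
            for rank, i in enumerate(idx_list, start=1):
                doc_id = result.doc_ids[i]
                doc = documents.get(doc_id)
                rows.append(
                    {
                        "rank": rank,
                        "doc_id": doc_id,
                        "title": doc.title if doc else "",
                        "probability_positive": float(
                            result.probability_positive[i]
                        ),
                    }
                )
            path = out / f"{name}.csv"
            pd.DataFrame(
                rows,
                columns=["rank", "doc_id", "title", "probability_positive"],
            ).to_csv(path, index=False)
            manifest[f"{name}_list"] = str(path)

        metrics = {"schema_version": 1}
        if result.tournament is not None:
            metrics["tournament"] = result.tournament.to_dict()
        metrics["winner"] = result.winner.name.value
        path = out / "metrics.json"
        path.write_text(json.dumps(metrics, indent=2))
        manifest["metrics"] = str(path)

        sig_rows = [
            {"class": "POSITIVE", "rank": r, "term": t, "score": s}
            for r, (t, s) in enumerate(signature.positive_terms, start=1)
        ] + [
            {"class": "NEGATIVE", "rank": r, "term": t, "score": s}
            for r, (t, s) in enumerate(signature.negative_terms, start=1)
        ]
        path = out / "signature.csv"
        pd.DataFrame(
            sig_rows, columns=["class", "rank", "term", "score"]
        ).to_csv(path, index=False)
        manifest["signature"] = str(path)

        path = out / "projection.csv"
        df = projection.to_frame()
        df["explained_var_pc1"] = projection.explained_variance_ratio[0]
        df["explained_var_pc2"] = projection.explained_variance_ratio[1]
        df.to_csv(path, index=False)
        manifest["projection"] = str(path)

        path = out / "run_log.json"
        path.write_text(json.dumps(run_log or {}, indent=2, default=str))
        manifest["run_log"] = str(path)
        return manifest
    except OSError as exc:
        raise IOFailure(f"failed writing outputs to {out}: {exc}") from exc
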