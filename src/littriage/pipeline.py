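"""End-to-end orchestration: ingest → preprocess → features → classify → report.

One :func:`run_pipeline` call reproduces a full triage run: three corpora in
(two labeled training sets, one to classify), ranked lists, term signature,
PCA coordinates, metrics and a replayable run log out. Runs are stateless;
the iterative-curation loop is realised by re-running with enlarged ID
lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import (
    Category,
    Corpus,
    Document,
    Transport,
    fetch_abstracts,
    parse_pmid_list,
    read_corpus_file,
)
from .classify import (
    ClassifierSpec,
    default_roster,
    fit_and_classify,
    run_tournament,
)
from .errors import LimitExceeded, OverlapError
from .features import (
    build_dtm,
    project_onto_vocabulary,
    restrict_to_terms,
    select_terms,
    tfidf_transform,
)
from .preprocess import PreprocessConfig, preprocess_corpus
from .report import pca_projection, term_signature, write_outputs

logger = logging.getLogger(__name__)

MAX_CLASSIFY_DEFAULT = 1000


@dataclass
class RunConfig:
    """All knobs of one pipeline run, echoed verbatim into run_log.json."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    top_terms: int = 1000
    folds: int = 5
    seed: int = 0
    max_classify: int = MAX_CLASSIFY_DEFAULT
    force: bool = False          # override the max_classify cap
    n_signature_terms: int = 25  # per class
    roster: list[ClassifierSpec] | None = None
    fixed_spec: ClassifierSpec | None = None  # skip the tournament if set
    out_dir: str | Path | None = None

    def provenance(self) -> dict:
        return {
            "preprocess": self.preprocess.provenance(),
            "top_terms": self.top_terms,
            "folds": self.folds,
            "seed": self.seed,
            "max_classify": self.max_classify,
            "force": self.force,
            "n_signature_terms": self.n_signature_terms,
            "fixed_spec": self.fixed_spec.name.value if self.fixed_spec else None,
        }


@dataclass
class PipelineResult:
    """Everything a run produced, before/after writing to disk."""

    classification: object
    tournament: object
    signature: object
    projection: object
    selections: list
    manifest: dict[str, str]


def load_corpora_local(
    pos_path: str | Path, neg_path: str | Path, classify_path: str | Path
) -> tuple[Corpus, Corpus, Corpus]:
    return (
        read_corpus_file(pos_path, Category.TRAIN_POS),
        read_corpus_file(neg_path, Category.TRAIN_NEG),
        read_corpus_file(classify_path, Category.CLASSIFY),
    )


def load_corpora_pubmed(
    pos_ids_text: str,
    neg_ids_text: str,
    classify_ids_text: str,
    transport: Transport,
) -> tuple[Corpus, Corpus, Corpus]:
    return (
        fetch_abstracts(parse_pmid_list(pos_ids_text), Category.TRAIN_POS, transport),
        fetch_abstracts(parse_pmid_list(neg_ids_text), Category.TRAIN_NEG, transport),
        fetch_abstracts(parse_pmid_list(classify_ids_text), Category.CLASSIFY, transport),
    )


def _check_inputs(
    train_pos: Corpus, train_neg: Corpus, classify: Corpus, config: RunConfig
) -> None:
    overlap = set(train_pos.doc_ids) & set(train_neg.doc_ids)
    if overlap:
        raise OverlapError(
            f"{len(overlap)} ID(s) appear in both training lists: "
            f"{sorted(overlap)[:5]}"
        )
    if len(classify) > config.max_classify and not config.force:
        raise LimitExceeded(
            f"classification list has {len(classify)} documents; the cap is "
            f"{config.max_classify} per run (pass force to override)"
        )


def run_pipeline(
    train_pos: Corpus,
    train_neg: Corpus,
    classify: Corpus,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Execute the full triage pipeline on three assembled corpora.

    Training documents keep their corpus labels; the classification corpus
    is treated as unlabeled. Artifacts are written when
    ``config.out_dir`` is set; the in-memory results are returned either
    way.
    """
    config = config or RunConfig()
    _check_inputs(train_pos, train_neg, classify, config)

    train = Corpus(
        train_pos.documents + train_neg.documents,
        Category.TRAIN_POS,
        train_pos.retrieval_log + train_neg.retrieval_log,
    )
    tc_train = preprocess_corpus(train, config.preprocess)
    tc_test = preprocess_corpus(classify, config.preprocess)

    counts = build_dtm(tc_train)
    weighted = tfidf_transform(counts)
    selections = select_terms(weighted, tc_train.labels, k=config.top_terms)
    kept = [s.term for s in selections if s.selected]
    x_train = restrict_to_terms(weighted, kept)

    if config.fixed_spec is not None:
        winner = config.fixed_spec
        tournament = None
    else:
        # tournament sees the full weighted matrix and re-selects terms
        # inside each fold, keeping the CV estimate leak-free
        tournament = run_tournament(
            weighted,
            tc_train.labels,
            config.roster or default_roster(),
            folds=config.folds,
            seed=config.seed,
            select_k=config.top_terms,
        )
        winner = tournament.winner
    x_test = project_onto_vocabulary(tc_test, x_train.vocabulary, counts)
    classification = fit_and_classify(
        x_train, tc_train.labels, x_test, winner,
        seed=config.seed, tournament=tournament,
    )

    signature = term_signature(
        weighted, tc_train.labels, n_per_class=config.n_signature_terms
    )
    projection = pca_projection(x_train, x_test, tc_train.labels, classification)

    manifest: dict[str, str] = {}
    if config.out_dir is not None:
        documents: dict[str, Document] = {
            d.doc_id: d
            for c in (train_pos, train_neg, classify)
            for d in c.documents
        }
        run_log = {
            "config": config.provenance(),
            "n_train_pos": len(train_pos),
            "n_train_neg": len(train_neg),
            "n_classify": len(classify),
            "n_selected_terms": len(kept),
            "winner": winner.name.value,
            "retrieval_log": {
                "train_pos": [(i, s.value) for i, s in train_pos.retrieval_log],
                "train_neg": [(i, s.value) for i, s in train_neg.retrieval_log],
                "classify": [(i, s.value) for i, s in classify.retrieval_log],
            },
        }
        manifest = write_outputs(
            classification, signature, projection, config.out_dir,
            documents=documents, run_log=run_log,
        )
    return PipelineResult(
        classification, tournament, signature, projection, selections, manifest
    )
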