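"""Exception hierarchy for the triage pipeline.

Every stage raises subclasses of :class:`TriageError`; the CLI maps each
class to a distinct nonzero exit code (see :mod:`littriage.cli`).
"""


class TriageError(Exception):
    """Base class for all pipeline errors."""


# --- corpus_io ---------------------------------------------------------------

class EmptyInput(TriageError):
    """An ID list contained no valid PubMed ID."""


class MalformedID(TriageError):
    """All tokens in an ID list were non-numeric."""


class NetworkError(TriageError):
    """Retrieval failed after bounded retries."""


class AllRecordsFailed(TriageError):
    """No document could be retrieved for any requested ID."""


class MissingColumn(TriageError):
    """A local corpus file lacks a required header column."""


class EmptyCorpus(TriageError):
    """A corpus contains no usable document."""


# --- features ----------------------------------------------------------------

class EmptyVocabulary(TriageError):
    """All token lists were empty; no document-term matrix can be built."""


class AlreadyWeighted(TriageError):
    """Tf-Idf transform applied to an already-weighted matrix."""


class EmptySample(TriageError):
    """A rank test was called with an empty sample."""


# --- classify ----------------------------------------------------------------

class SingleClassInput(TriageError):
    """Training labels contain only one class."""


class TooFewDocuments(TriageError):
    """A class has fewer documents than cross-validation folds."""


class VocabularyMismatch(TriageError):
    """Train and test matrices do not share an identical vocabulary."""


# --- evaluate ----------------------------------------------------------------

class SingleClassTruth(TriageError):
    """Truth labels contain a single class where two are required."""


class SizeExceedsCorpus(TriageError):
    """A requested subsample size exceeds the corpus."""


class OddSize(TriageError):
    """Balanced subsampling requires an even size."""


class RatioSumMismatch(TriageError):
    """An imbalance ratio does not sum to the stated total."""


# --- synthetic ---------------------------------------------------------------

class InvalidConfig(TriageError):
    """A generator or run configuration is invalid."""


# --- pipeline ----------------------------------------------------------------

class OverlapError(TriageError):
    """A document ID appears in both training lists."""


class LimitExceeded(TriageError):
    """The classification list exceeds the per-run document cap."""


class IOFailure(TriageError):
    """Writing a result artifact failed."""
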