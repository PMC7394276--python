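# Methods

`littriage` classifies article abstracts into two user-defined classes
(e.g. *relevant* / *irrelevant* to a database-curation task) from two
labeled training corpora, and ranks an unlabeled corpus by class
probability. This note records the statistical procedure, the choices made
where the design was genuinely open, and what the synthetic test bed does
and does not establish.

## Pipeline

1. **Ingestion.** Corpora arrive as PubMed ID lists (abstracts fetched via
   NCBI efetch, batches of ≤200 IDs, ≥0.34 s between requests) or as local
   CSV files with columns `id,title,abstract`. Records without an abstract
   are excluded and logged; every requested ID is accounted for in the
   retrieval log (`OK` / `NO_ABSTRACT` / `NOT_FOUND`). The text fed
   downstream is `title + " " + abstract` (titles carry signal and are part
   of the retrieved record); an abstract-only mode is available.

2. **Preprocessing.** Five operations, in order: lowercase folding (NFKC
   normalised), punctuation removal, whitespace tokenisation, stopword
   removal, Porter stemming. Standalone digit strings are dropped, but
   tokens mixing letters and digits (p53, CD8) are kept intact — gene and
   marker names are among the most informative terms in biomedical text.
   Punctuation is *deleted in place* by default (so hyphenated words
   concatenate: `t-cells → tcells`), matching the behaviour of classic
   text-mining toolkits; a mode replacing punctuation with spaces is
   provided because concatenation can fuse distinct words. Stopwords are
   removed before stemming (stopword lists contain unstemmed English
   words). The default stopword lexicon is scikit-learn's frozen built-in
   English list (318 words); any list can be loaded from a one-word-per-line
   file for exact reproduction of other setups.

   The stemmer is a self-contained implementation of Porter's 1980
   algorithm, validated against the algorithm's published example pairs.
   Note that Porter stemming is not a fixed-point map on arbitrary English
   (`agreed → agre`, and `agre` re-stems to `agr`), so "preprocessing is
   idempotent" holds on token streams whose words are stem-stable — which
   the synthetic generator guarantees by construction — not universally.

3. **Features.** Raw token counts per document over the lexicographically
   sorted corpus vocabulary, then Tf-Idf weighting

   w(t, d) = (count(t, d) / len(d)) · log2(N / df(t)),

   the classic length-normalised variant: a term present in every document
   carries zero weight, zero-length documents stay zero rows. Unlabeled
   documents are projected onto the *training* vocabulary and weighted with
   the training corpus's df and N, so train and test features are
   commensurable; unseen terms are dropped and fully out-of-vocabulary
   documents are flagged.

4. **Term selection.** Per term, a two-sided Mann-Whitney U test compares
   the Tf-Idf weight distributions of the two training classes. U follows
   the rank-sum convention U = R_a − n_a(n_a+1)/2 with midranks for ties.
   P-values are exact (counting recursion over the U distribution) for
   tie-free samples with n_a+n_b ≤ 12, and otherwise use the normal
   approximation with midrank tie correction and 0.5 continuity
   correction. Terms are ranked by ascending p, ties broken by descending
   absolute mean-rank difference, then lexicographically; the top
   k = min(1000, |vocabulary|) are kept (k is the `--top-terms` knob; the
   value is large enough to feed all ten classifier families and small
   enough to tame the p ≫ n regime). No multiple-testing correction is
   applied: this is selection, not inference — a monotone transform of the
   p-values would select the same set.

5. **Classifier tournament.** Ten families — linear SVM, elastic-net
   logistic regression (glmnet-style, mixing parameter 0.5), maximum
   entropy (= multinomial logistic regression), scaled linear discriminant
   analysis (standardise, then LDA with the SVD solver, which tolerates
   singular covariances), bagging of trees, boosting (AdaBoost), random
   forest, k-nearest neighbour, a single decision tree, and multinomial
   naive Bayes — are trained on identical stratified five-fold splits and
   ranked by mean CV accuracy (sensitivity, specificity and F1 are
   reported alongside). Ties go to the earlier algorithm in the canonical
   listing (priority 1–10). Hyperparameters are library defaults, pinned
   and echoed into the run log. A learner that fails on a fold scores 0
   for that fold and the failure is logged.

   **Nested selection.** The U-test selection is re-run *inside each CV
   fold* on that fold's training rows only. Selecting on the full label
   vector first and cross-validating afterwards leaks label information
   when terms outnumber documents ~10:1 — on no-signal corpora the leaked
   CV accuracy reaches 0.93 for the linear learners — so the nested form
   is the only honest CV estimate. The final model is still fit on the
   globally selected terms, which is safe because the held-out corpus
   plays no part in selection.

   The winner is refit on the full training matrix; test documents get a
   probability of the positive class (margin-only learners are passed
   through a one-dimensional logistic link fitted on training decision
   values — monotone, so ranking is exact and calibration best-effort).
   Assignment is positive iff p ≥ 0.5; each output list is sorted by
   descending confidence with doc-id tie-breaks for determinism.

6. **Reports.** (a) `positive.csv` / `negative.csv`: rank, id, title,
   probability. (b) The term signature: the 25 terms per class with the
   largest mean Tf-Idf difference between classes (the data behind a
   word-cloud display; a U-statistic ranking is available via config).
   (c) PCA of the stacked, column-mean-centred weighted matrix (combined
   train+test fit by default, train-only fit available); components are
   unscaled because unit-variance scaling would inflate rare terms, and
   component signs are fixed by forcing each component's largest-magnitude
   loading positive, making coordinates reproducible.

Runs are stateless; the iterative curation loop (grow the training lists,
re-run) is realised by re-running the pipeline. The 1000-document cap on
the classification list is a soft default from the original service
setting, overridable with `--force`.

## Synthetic corpora

Real curation corpora are proprietary, so the test bed generates two-class
corpora with known ground truth:

- **Background vocabulary**: V = 2000 pseudo-words with Zipf-distributed
  frequencies (weight ∝ rank^−1.1), the heavy-tailed profile of real word
  frequencies.
- **Signal terms**: 50 per class, disjoint, planted at the base weight of
  the rank-⌈V/4⌉ background term (mid-frequency, like realistic
  informative terms); in their own class the weight is multiplied by the
  enrichment factor. Enrichment 1 makes the class distributions identical
  (null); enrichment is the single separation knob.
- **Documents**: length ~ Poisson(150) tokens (typical abstract length),
  i.i.d. token draws; first three tokens serve as the title.
- **Vocabulary construction**: consonant-vowel pseudo-words filtered to be
  stopword-free and Porter-stable, so ground-truth terms survive
  preprocessing unchanged and remain traceable end to end.

The benchmark suite fixes three recipes — easy (enrichment 10), hard (2),
null (1) — each 2000 documents split 1500 train / 500 held-out, balanced,
mirroring a 3:1 train/evaluation split of a 2000-abstract corpus.

What this does **not** emulate: burstiness (within-document token
clumping), correlated term co-occurrence, multi-word expressions, section
structure, and label noise. Passing tests demonstrate the machinery is
correct and calibrated under the stated generative model, not that any
particular accuracy will be reached on real literature.

## Evaluation design

- Accuracy/sensitivity/specificity/F1 from the confusion matrix at
  threshold 0.5; AUC from the rank statistic (Mann-Whitney identity,
  midranks for ties), cross-checked against trapezoidal ROC integration on
  every call. Single-class truth yields a missing AUC, not an error.
- Learning curves and imbalance sweeps subsample a labeled pool and score
  on a *fixed* held-out set, so curve noise reflects training-set sampling
  only. Within a replicate, subsamples are **nested** across sizes (one
  permutation per class, prefixes taken), and ratios share permutations —
  a paired design under which consecutive points share documents and
  size-to-size noise largely cancels.
- Default replicate counts in the shipped experiments (10 for imbalance,
  5 for curves) are the package's desk-scale choice; larger values are a
  flag away.

## Calibration probes

On null corpora the tournament's CV accuracies are checked against
chance within 3 binomial standard errors of a 200-document estimate. The
U-test false-positive rate at α = 0.05 is checked over terms present in at
least 10% of documents: on rarer terms the weight vector is almost all
zeros, the tie-corrected statistic is discrete and intrinsically
conservative, and a two-sided check around the nominal level would probe
discreteness rather than calibration.

## Known limitations

- Probability calibration for margin-only learners is best-effort; the
  ranking, not the absolute probability, is the contract.
- No hyperparameter search; the tournament compares pinned defaults.
- glmnet-style elastic net is solved by stochastic gradient descent with a
  fixed penalty (α = 10⁻⁴, mixing 0.5), not by a regularisation path with
  internally cross-validated λ.
- Two classes only; multi-class selection and classification are out of
  scope.
- The Entrez transport is exercised in tests only through the injected
  fixture backend; live retrieval shares all parsing code but not the
  network path.
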