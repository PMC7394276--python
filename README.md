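# littriage

Two-class triage of biomedical literature: rank a pile of unread abstracts
by their probability of being relevant to your curation task.

Database curators and reviewers routinely face PubMed query results far
larger than anyone can read. When a project has already sorted some
articles into *relevant* and *irrelevant* piles, those piles are training
data. `littriage` turns them into a classifier and applies it to the
unread pile, so curators spend their time on the articles most likely to
matter — and the sorted output of each round grows the training set for
the next.

## Method

Given a positive corpus, a negative corpus, and a corpus to classify
(PubMed ID lists, fetched via NCBI E-utilities, or local CSV files):

1. **Preprocess** each abstract: lowercase, remove punctuation, tokenize,
   drop stopwords, Porter-stem. Standalone numbers are dropped, but
   letter–digit tokens (p53, CD8) are kept — gene names are signal.
2. **Weight** the document-term matrix by Tf-Idf:
   `w(t,d) = (count(t,d)/len(d)) · log₂(N/df(t))`.
3. **Select terms** by a per-term two-sided Mann-Whitney U test between
   the two training classes; keep the top *k* (default 1000) by p-value.
4. **Pick a classifier** by five-fold stratified cross-validation over ten
   families — SVM, elastic-net logistic regression, maximum entropy,
   scaled LDA, bagging, boosting, random forest, k-NN, decision tree,
   naive Bayes — all on identical folds, with term selection re-run inside
   each fold so the CV estimate is leak-free.
5. **Classify and rank** the unlabeled corpus with the winner, and report
   two probability-ranked lists, the 50-term differential signature
   (25 per class), per-algorithm CV metrics, and 2-D PCA coordinates
   showing class separation.

A synthetic-corpus generator (Zipf background vocabulary + class-enriched
planted terms with a tunable enrichment knob) provides ground-truth test
beds, so the whole pipeline is testable offline. See `docs/methods.md`
for the statistical details and design rationale.

## Worked example

Generate a synthetic corpus, split it, and run the pipeline:

```bash
littriage simulate --docs-per-class 120 --enrichment 6 --seed 7 --out corpus.csv
# split corpus.csv into train_pos.csv / train_neg.csv (90 docs each)
# and unknown.csv (60 docs), then:
littriage run --pos train_pos.csv --neg train_neg.csv --classify unknown.csv \
    --local --top-terms 500 --seed 1 --out results
```

The run prints a manifest of the written artifacts. Inspecting them:

```text
$ head -4 results/positive.csv
rank,doc_id,title,probability_positive
1,P00093,babab babag bazap,0.7219173906795687
2,P00107,bafam babod babab,0.7022268446115549
3,P00092,babab baboz babut,0.6989916749188458

$ python -c "import json; m=json.load(open('results/metrics.json')); print(m['winner'])"
SVM

$ head -4 results/signature.csv
class,rank,term,score
POSITIVE,1,dazol,0.005222164523205038
POSITIVE,2,dobam,0.004837156903408529
POSITIVE,3,dazop,0.0047221938305324635
```

Here the SVM won the tournament with mean CV accuracy 0.972 (elastic-net
and maximum-entropy tied; the tie-break follows the canonical algorithm
order), all 60 held-out documents were assigned their true class, and the
top signature terms are exactly the generator's planted class-specific
terms (`dazol`, `dobam`, ... belong to the positive class's signal set in
`corpus.truth.json`). `probability_positive` is the winner's calibrated
probability that a document belongs to the positive class; `positive.csv`
is sorted descending, `negative.csv` ascending, so each list reads from
most to least confident.

Output files per run: `positive.csv`, `negative.csv` (rank, doc_id,
title, probability_positive), `metrics.json` (per-algorithm fold
accuracies, winner, hyperparameters), `signature.csv` (class, rank, term,
mean Tf-Idf difference), `projection.csv` (doc_id, pc1, pc2, role,
explained variance), `run_log.json` (full configuration echo).

## CLI summary

- `littriage run` — full pipeline (`--local` CSV corpora or `--pubmed` ID
  lists; `--algorithm` to skip the tournament; `--top-terms`, `--folds`,
  `--seed`, `--max-classify`/`--force`, `--out`).
- `littriage fetch` — download an ID list into a local corpus CSV.
- `littriage simulate` — generate a labeled synthetic corpus plus ground
  truth sidecar.
- `littriage evaluate` — learning-curve and class-imbalance experiments on
  labeled corpora.

Exit codes: 0 success; distinct nonzero codes per error class (overlap
between training lists, classification-list cap, malformed inputs,
retrieval failures).
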