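# Methods

This note records the model, the defaults and the design choices behind
`expotext`, and what the synthetic-data experiments do and do not show.

## Classification model

Each taxonomy node is a binary classification problem over abstracts. A
document is represented as a sparse binary vector of presence features
(section below); a support-vector machine with an RBF kernel
`K(x, x') = exp(-γ‖x − x'‖²)` is trained per node, and a document is
labelled positive when the decision function exceeds zero. Nodes are
trained and applied independently, so the multi-label output is mutually
non-exclusive and no parent/child consistency is forced at prediction time
(`hierarchy_closure=True` adds post-hoc upward closure, intended for
profile building).

Training labels use hierarchical propagation: the upward closure of a
document's annotation through the taxonomy. Consequently a parent node's
positive set always contains the union of its descendants' positive sets.
Documents reviewed but judged irrelevant (explicit empty label sets) are
negatives for every node. Nodes with a single training class are skipped
with a warning rather than trained.

Implementation note: training uses precomputed kernels — pairwise squared
distances are computed once per training split and `K = exp(-γD)` is formed
per gamma. This is algebraically identical to evaluating the kernel inside
each SVM fit and is shared across all nodes, grid points and inner folds.
Fitted models store their support vectors (as active-index lists, since
vectors are binary), dual coefficients and intercept; prediction evaluates
the standard kernel expansion, so saved and in-memory models agree exactly.

## Features

Seven families, all with strict presence (0/1) semantics — repeated
occurrences in one abstract change nothing, and no TF or TF-IDF weighting
is applied anywhere:

* **LBOW** — one feature per distinct token lemma.
* **NBIGRAM** — adjacent noun-tagged surface pairs, case-folded but never
  lemmatized, so noun compounds keep their concept reading
  ("drinking water", not "drink water").
* **GR** — for every dependency arc, the lexicalized triple
  `(relation, head, dependent)` plus the two single-wildcard variants
  `(relation, head, *)` and `(relation, *, dependent)`. Both forms are
  emitted deliberately: the wildcard patterns generalize across lexical
  variation while document-frequency selection prunes whichever form is
  uninformative for a node.
* **NE** — `(entity_type, span)` pairs over the five biomedical entity
  types (DNA, RNA, protein, cell line, cell type); spans keep their
  verbatim surface.
* **VC** — a verb lemma found in the 3-level semantic verb hierarchy
  activates one bit per level, so clustered verbs ("stimulate",
  "activate") share all three bits. The shipped baseline lexicon covers
  56 common biomedical verbs in 3-level classes; a larger reference
  lexicon (e.g. a 399-verb biomedical verb hierarchy) can be supplied as a
  TSV (`verb<TAB>L1<TAB>L2<TAB>L3`) and used unchanged.
* **MESH / CHEM** — MeSH descriptors and chemical-substance names from the
  PubMed record, case-folded verbatim.

All feature values are case-folded except NE spans.

### Feature selection

Per node, a feature is retained when its document frequency in the node's
training corpus lies in `[min_df, max_df]`. Defaults: `min_df = 5`
documents; `max_df = 0.30` as a fraction of the corpus (the scale-free
analogue of an absolute cap of a few hundred documents on a few-thousand
document corpus). Both are overridable globally and per family.
Frequencies are counted over documents, not occurrences. Selection is
computed independently per node; with identical thresholds the selected
sets coincide, but changing one node's thresholds can never affect
another's vocabulary.

## NLP baselines

The five annotation stages are adapter contracts with deterministic
rule-based baselines, so the pipeline runs without model downloads and its
outputs are exactly reproducible:

* cleaning: NFKC normalization, control characters stripped, whitespace
  collapsed (idempotent);
* tokenization: regex tokenizer keeping decimal numbers and
  hyphen/apostrophe-internal words intact; sentence boundaries at terminal
  punctuation with an abbreviation stop list;
* POS: closed-class lexicon → verb-lexicon inflection matching → suffix
  heuristics → default `NN`; a gerund directly before a noun is retagged as
  a noun-compound modifier;
* lemmas: irregular-form exceptions, then POS-aware suffix stripping with
  e-restoration against the known verb set;
* NER: longest-match non-overlapping gazetteer matching;
* parsing: finite-state subject–verb–object matcher emitting `subject`,
  `object` and intra-noun-group `modifier` arcs. The relation inventory is
  deliberately small; external adapters may emit richer label sets.

These baselines are not replacements for trained biomedical NLP tools in
accuracy; they exist to make the feature and classifier design — the part
this package is about — fully testable and deterministic. Classification
text is the abstract only by default (`include_title=True` prepends the
title); records without an abstract are excluded from training and
evaluation by default.

## Hyperparameter tuning

Per node, `(C, γ)` is selected from the grid `C ∈ {0.1, 1, 10, 100}`,
`γ ∈ {0.001, 0.01, 0.1, 1}` (configurable) by stratified inner
cross-validation (default 5 folds) maximizing mean inner-fold F-score.
Ties break toward the smaller `C`, then the smaller `γ` — the least
complex model among equals — which also licenses stopping the grid scan
early once a perfect inner score is reached. The inner fold count is
reduced automatically when the minority class is smaller than the fold
count; with fewer than two minority examples the smallest grid point is
used. No class reweighting is applied by default
(`class_weight="balanced"` is available).

## Evaluation

The intrinsic evaluation is an outer k-fold cross-validation with
vocabulary building, feature selection and tuning performed strictly
inside each training split. The default is `k = 3`. (The source
methodology describes a four-fold setup while its headline results table
is reported under 3-fold cross-validation; both are supported via the `k`
parameter and the default follows the results table.) Per-node confusion
counts are pooled across folds before computing metrics — stabler for rare
nodes — with per-fold averaging available (`aggregate="mean"`). A
zero-denominator ratio is reported as 0 and named in a flags column. The
accuracy denominator is all documents in the evaluated set.

Feature ablation repeats the identical cross-validation with one family
excluded from vocabulary building and encoding; the family's influence is
the baseline mean F minus the ablated mean F. Removing a family that never
fires on a corpus reproduces the baseline per-node results byte-for-byte
(the run manifest necessarily differs, as it names the removed family).

Inter-annotator agreement is per-node Cohen's kappa on the 2×2 table after
closing both annotators' labels upward, `κ = (p_o − p_e)/(1 − p_e)` with
`p_e` from marginal products; perfect observed agreement is reported as
κ = 1 even when both marginals are degenerate, and the summary is the
unweighted mean over nodes with defined kappa. The closed form is
cross-checked against `sklearn.metrics.cohen_kappa_score` in the tests.

Retrieval comparison reports, for a node and a reference PMID list, the
`found/total` count of reference documents the classifier labelled with
that node, plus the missing PMIDs.

## Publication profiles

A profile counts, per taxonomy node, the documents predicted positive for
that node among all documents predicted positive for at least one node
("relevant"); percentages are against the relevant total and do not sum to
100 under multi-label output. Documents are counted once per node (not
once per branch). Profile matrices stack chemicals column-wise in taxonomy
traversal order and flag zero-count cells as candidate data gaps.

## Synthetic corpora

The generator emulates the *structure* of an annotated exposure corpus,
not its linguistic content: per chosen leaf it emits abstracts built from
subject–verb–object templates in which each noun slot produces one of the
leaf's 8 signal keywords with probability `signal_prob` (default 0.8) and
a background noun otherwise; verbs come mostly from the verb-cluster
lexicon and a fraction of background nouns are gazetteer entries, so the
GR, VC and NE families are exercised end to end. Node-correlated MeSH and
chemical strings are attached with configurable rates (defaults 0.6 /
0.4), every document carries uncorrelated background MeSH noise, 10% of
positive documents receive a second leaf label, and an irrelevant pool
draws background vocabulary only. Defaults: 150 documents per leaf plus
300 irrelevant. A second template mode (`lbow_only`) emits verb-less
comma-separated term lists in which keywords are never adjacent, so the
planted signal is carried by unigrams alone — this is the corpus used to
show that ablating LBOW produces the largest F drop. With one keyword slot
per emission, the probability a positive document contains at least one of
its keywords is `1 − (1 − signal_prob)^slots`, which the tests check at
binomial tolerance.

Passing these experiments shows that the pipeline recovers planted,
strongly separable signal and that its bookkeeping (closure, selection,
pooling, determinism) is correct. It does not show performance on real
PubMed abstracts, whose token distributions, annotation noise and class
overlap the generator deliberately does not imitate.

The second-annotator generator flips each (document, node) membership
independently with a given disagreement rate, giving closed-form expected
kappas (e.g. rate 0.05 at prevalence ½ gives κ ≈ 0.9).

## Problem sizes and statistical checks

The package's own experiment battery (test suite and
`scripts/acceptance.py`) uses: 1,000-document random label/prediction sets
for the metric and closure oracles; a 6-leaf × 150 + 300-document corpus
for recovery (3-fold outer, 5-fold inner CV, full default grid) and for
the ablation; 1,000-document annotator pairs for kappa. The permutation
null is checked as |precision − prevalence| ≤ 4σ binomial per node on
pooled predictions, with zero-prediction nodes treated as vacuous (no
precision evidence). Determinism checks compare byte-level serializations
(corpus bundles, model bundles, fold assignments, evaluation reports)
across two runs with the same seed.

## Known limitations

* The baseline NLP stages are intentionally simple; GR/NE/VC features on
  real text will be far noisier than on the synthetic templates.
* Branch-root classifiers are trained on the union of direct and
  propagated positives; whether the original system distinguished these is
  not resolvable from the available description.
* No probability calibration; decisions are raw SVM signs.
* No importers are provided for third-party annotated-corpus layouts;
  `read_corpus_bundle` defines this package's own canonical bundle, and
  the generic PubMed XML / MEDLINE readers cover records exported from
  PubMed directly.
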