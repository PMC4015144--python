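# Methods

This note documents the models, the synthetic data, the defaults and the
judgment calls behind `patentsearch`, in the spirit of a model/methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Retrieval model

Documents are bags of processed tokens from a configurable field scope:
TAC (title + abstract + claims) or TACD (TAC + description). Processing is
fixed and bit-exact so that index and query sides always agree:

1. **Tokenization**: lowercase, split on any character that is not a
   Unicode letter or digit. Numbers are kept — chemical names fragment
   into digit tokens ("pyrimidine-2,4-diamine") and dropping them loses
   signal for no benefit.
2. **Stopword removal** before stemming, using a shipped ~120-word English
   function-word list (overridable per `IndexConfig`); the list is
   deliberately minimal because patent claims lean on ordinary words.
3. **Stemming**: the classic Porter (1980) algorithm, authored in-package
   and checked against published test vectors.

Two kinds of pseudo-token join the text tokens and are never stemmed or
stopword-filtered, because they are identifiers, not words:

* `CONCEPT_<source>_<id>` — dictionary-normalized concepts, included when
  the index's `metadata_mode` (TAC/TACD) matches the scope the corpus was
  annotated with. Concepts are stored as a *bag* (duplicate mentions
  kept), so indexed metadata competes with text tokens under tf-based
  weighting rather than acting as a binary flag.
* `IPC_<code>` — each raw IPC code (e.g. `C07D 239/47`) yields a subclass
  token (`IPC_C07D`) and a full compacted-code token (`IPC_C07D239/47`),
  giving class-level and group-level match granularity.

### Term weighting

**BM25** uses natural-log idf floored at zero: `max(0, ln((N−df+0.5)/(df+0.5)))`.
The floor prevents terms occurring in more than half the collection from
*subtracting* score; nothing else is clamped. Defaults `k1=1.2`, `b=0.75`
are the standard values of the platform family this engine is modeled on;
both are exposed as parameters.

**PL2** uses base-2 logs throughout, `tfn = tf·log2(1 + c·avdl/dl)` with
`c=1.0` by default, and the Poisson/Laplace/Stirling form given in the
README. The value is reported exactly as computed, with no floor. A note
on sign: because the bracketed quantity is `−log2` of a (Stirling-
approximated) Poisson probability, its minimum over `λ` — attained at
`λ = tfn` — is about `0.76/(tfn+1)`, so in practice PL2 contributions are
positive; the no-floor policy is still stated explicitly because it is a
behavioural contract, not an accident.

**Retrieval** is term-at-a-time accumulation over postings; documents with
total score ≤ 0 are omitted; results are the top `k` (default 1000) by
(score descending, doc id ascending). The ascending-id tie-break makes run
files byte-reproducible. A query that is empty after processing and a
query whose every term is out of vocabulary raise *different* errors; the
batch runner (`run_search`) converts the all-OOV case into an empty result
list so one degenerate topic cannot abort a benchmark run.

`score_document_bruteforce` re-derives any document's score by direct
per-term lookup with no posting traversal; the test suite holds the two
paths equal to 1e-9 relative, for both models.

## Normalization

Dictionary normalization is exact gazetteer matching: terminology terms
are tokenized with the engine's own tokenizer and matched against the
scoped, tokenized document text greedily, leftmost-longest,
non-overlapping (scanning resumes after each match). No stemming or fuzzy
matching of terms — dictionary lookup is the method being modeled, and
anything cleverer behaves differently per entity type and becomes hard to
audit. Matches from different terminologies may overlap; their union is
kept. Annotation replaces (never appends to) a document's metadata, which
makes it idempotent.

## Co-citation re-ranking

`compute_citation_counts` counts, per patent, the distinct in-collection
patents citing it (self-citations and dangling citations ignored). Within
a retrieved list, retrieval score and damped citation count
(`log1p` by default — raw counts are heavy-tailed and would saturate
min-max scaling) are each min-max normalized; a component with no spread
normalizes to all zeros. The final score is `(1−α)·s_ir + α·s_cit`,
`α = 0.2` by default: a modest prior-popularity boost; `α` is a flag.
Combination is in score space, within the retrieved set only — re-ranking
is a permutation of the list, never an expansion with unretrieved cited
patents. At `α = 0` it is the identity.

## Benchmarks and metrics

* **Prior art (PA)**: topics are patents with ≥ 1 in-corpus citation;
  qrels are the cited-in-corpus sets, excluding the topic patent itself.
  The query is the topic patent's full TAC token bag; by default the
  source patent is removed from its own result list (it trivially matches
  itself).
* **Known-item (KI)**: 10 distinct words sampled uniformly from a
  patent's TAC tokens; eligibility excludes stopwords and single
  characters, since a topic of ten stopwords tests nothing. The source
  patent is the single relevant document.
* **Technical survey (TS-style)**: the same sampling machinery with *a
  few* keywords (4 by default) and the source patent's IPC codes attached
  to the topic — short ambiguous queries are the regime where class codes
  can disambiguate.

Metrics use 1-based ranks internally: reciprocal rank, non-interpolated
average precision at cutoff 1000, and P@1. P0 is the mean reciprocal rank;
for single-relevant topics AP ≡ RR, which the suite asserts across whole
KI benchmarks. Topics with empty qrels are excluded from means (AP is
undefined at R=0) and reported in a separate count. **Run files store a
0-based rank column** — the convention under which the engine family's
reported example ranks are arithmetically consistent with its reported AP
values — and the run reader ignores that column entirely, re-sorting by
(score desc, id asc).

Significance between two configurations is a two-sided paired sign-flip
randomization test on the mean per-topic difference: exact enumeration of
all `2^n` sign patterns for `n ≤ 20` (vectorized in 65k-mask chunks),
seeded Monte Carlo with the observed assignment counted (`p ≥ 1/(B+1)`)
above that. Comparisons use `|stat| ≥ |observed| − 1e-12` so floating-point
noise cannot drop the observed pattern itself.

## Synthetic corpus

The generator emulates the structure that makes the tuning strategies
meaningful, not patent language:

* **Topical clusters.** Each patent belongs to one of `n_topics = 10`
  latent topics; TAC fields draw ~90% of tokens from the topic vocabulary
  (100 words, Zipf-like 1/rank weights) and ~10% from a shared noise
  vocabulary (500 words).
* **Vocabulary ambiguity.** 30% of each topic's vocabulary
  (`vocab_overlap_frac = 0.3`) is drawn from a shared pool, so one word
  can belong to several topics. Real technical vocabulary spans patent
  classes; without this overlap every content word would identify its
  topic uniquely and class codes could never add information — an IPC
  ablation on such a corpus would be vacuous.
* **Long noisy descriptions.** Expected field lengths are title 8,
  abstract 60, claims 120, description 600 tokens, with 80% of
  description tokens from the noise vocabulary. This is the mechanism by
  which indexing the description dilutes precision while inflating index
  size — the premise of the field-selection experiment.
* **Citation network.** Each patent cites `Poisson(3)` earlier patents
  (the graph is acyclic by construction); a citation targets a same-topic
  patent with probability 0.9 and is drawn with probability proportional
  to `(in-degree + 1)^1.0` (preferential attachment). Citation-derived
  relevance is therefore topical *and* concentrated on highly cited
  patents — the premise of co-citation boosting.
* **IPC codes** are a deterministic function of the topic (2 per patent),
  so they are a clean class signal.
* **Terminology**: concepts are 1–3-token phrases sampled from the corpus
  TAC text (so every concept is findable), plus generated synonyms.

All randomness flows from one integer seed through named substreams
(vocabulary, text, citations, terminology), so identical configs produce
byte-identical corpora.

**What passing tests do not show**: the generator has unigram text, no
claim grammar, no chemistry, no multilingual content, and its relevance is
citation-complete by construction (real prior-art qrels are incomplete).
Directional conclusions — description hurts known-item precision,
co-citation boosting helps prior-art search, IPC helps short ad-hoc
queries — transfer as mechanisms; absolute P0/MAP values do not.

## Experiment grid

Desk-scale defaults: 300 patents, 50 PA topics, 100 KI/TS topics, cutoff
1000 — minutes-scale on one core. The grid's rows mirror the classic
tuning stages (description in/out, metadata NONE/TAC/TACD, PL2 vs BM25,
co-citation on/off, IPC on/off), but every delta is a **single-knob paired
comparison**: a row and its declared baseline differ in exactly one
strategy, with everything else held at the winning setting of earlier
stages (no description, no metadata, BM25). A sequential "apply IPC on top
of whatever won so far" chain would confound the IPC delta with the
re-ranking delta and is data-dependent; a fixed factorial pairing is
reproducible and feeds the paired significance test directly. The metadata
rows make no directional claim — the grid reports whatever the corpus
yields there (dictionary normalization is expected to be roughly neutral).

## Known limitations

* One bag-of-tokens index field; no fielded or positional scoring, no
  incremental indexing, no compression.
* Exact-match normalization only: no disambiguation, abbreviation
  expansion or approximate matching.
* Re-ranking never injects cited-but-unretrieved patents.
* The stopword list and tokenizer are this package's own specification;
  absolute scores will differ from any other engine even on identical
  data. Only properties and synthetic-corpus behaviour are claimed.
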