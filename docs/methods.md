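# Methods

## The model

`semrank` re-ranks text-based medical image search results. The pipeline
has three stages.

**1. Concept representation.** Queries and image captions are reduced to
Medical-Dependent Features (MDF): a fixed, ordered catalogue of 87
categorical values in 9 facets (radiology modality, microscopy type,
visible-light photography, printed signals, generic biomedical
illustrations, dimensionality, colour, test specifics, condition
specifics). Text is mapped to the catalogue by deterministic dictionary
matching — case-insensitive, token-boundary, longest-match-first, with a
shipped synonym table for clinical abbreviations (MRI, CT, PET, EEG, ...).
This replaces concept-extraction services (MetaMap/UMLS): it is fully
reproducible and needs no external infrastructure, at the cost of
recognizing only catalogued surface forms (no spelling correction, no
negation or part-of-speech handling).

An item with binary presence vector `V` over the catalogue is expanded
against a semantic similarity matrix `SSM` (one similarity per unordered
feature pair, symmetric, entries in [0, 1], unit diagonal) into the
feature matrix `NQM[i][j] = V[i] * SSM[i][j]`. External matrices (e.g.
Resnik information-content similarities computed offline) are loaded from
TSV, symmetrized by averaging and min-max normalized over the
off-diagonal, because raw information-content similarities are unbounded
and path tools can emit asymmetric estimates; `normalize=False` preserves
the raw scale. A seeded fixture generator substitutes for an ontology
export: baseline pair similarities are drawn from Beta(1, 12) (heavily
right-skewed, mean ≈ 0.08 — most concept pairs share almost nothing) and
pairs within one catalogue facet get a boost (default 0.5) before
clipping, emulating ontology neighbourhoods.

**2. Matching.** Twelve scalar filters summarize a (query Q, document D)
pair: corpus co-occurrence confidence (CoQF, CoDF), length-normalized
overlap (LQF — requiring Q ⊆ D — and LDF), inverse baseline rank (RQF)
and in-document query frequency with an order-preservation factor γ
(RDF), positional proximity (PQF) and inverse shared-feature count (PDF),
mean pointwise mutual information (PMIQF with the collection size as N,
PMIDF with the document length as N), and feature-difference penalties
(FDQF = 1/(1+|Q∖D|), FDDF = 1/(1+|D∖Q|)). Set semantics are used wherever
the definition counts features; occurrence order and multiplicity enter
only through PQF and RDF. All degenerate cases (empty sides, zero
denominators, no PMI evidence) return 0, so every filter is total. PMI is
natural-log; pairs without co-occurrence evidence are skipped from the
mean rather than coerced to zero.

Each side's six filter scores are pushed through a small forward pass:
the score is expanded to an n-vector (masked by the item's active
features, or broadcast), convolved against the rows of the item's NQM
(one dot product per row), rectified, max-pooled to a scalar, and the six
pooled scalars pass through a fully connected layer. Nothing in the model
defines a training signal — there are no labels, no loss — so the layer
defaults to identity weights and zero bias and the network is a
deterministic feature aggregator; a seeded random weight matrix exists
for ablations only. The matching score is the cosine of the two
representations, and the final score fuses it with the BM25 baseline:

    SemRank(d) = α · bm25(d)/max bm25  +  (1−α) · dmm(d)/max dmm

with the maxima over the query's candidate list and α = 0.3 by default.
Candidates come from a native Okapi BM25 pass (k1 = 1.2, b = 0.75,
idf = ln(1 + (N−df+0.5)/(df+0.5)) so idf is never negative; the
per-query max-normalization in the fusion absorbs the idf variant). Ties are broken by higher baseline
score, then document id, making runs byte-reproducible.

**3. Evaluation.** TREC-style runs and qrels; MAP, P@5, P@10 with
trec_eval conventions (P@k divides by k even for short lists; queries
without relevant documents are skipped from MAP with a warning; binary
relevance is grade > 0). Paired run comparison uses the two-sided
Wilcoxon signed-rank test on per-query average precision, dropping zero
differences; fewer than two non-zero pairs is reported as undefined
rather than significant.

## A structural property of the untrained network

With identity weights and zero bias the forward pass admits a closed
form: every filter's feature map is `score_t × u` for the single vector
`u = V ⊙ (SSM·V)`, so the pooled vector is `max(u) · max(scores, 0)` and
the common factor `max(u)` — the only place the semantic matrix enters —
cancels in the cosine. The matching score therefore depends only on the
*direction* of the two clipped filter-score vectors, not on their
magnitude and not on the semantic matrix. Empirically this direction
statistic is a weak ranker: components that are positive for every
document (the feature-difference filters, the query-independent PMIDF)
align even for documents with no shared evidence, while well-evidenced
documents are penalized by their own norm. On the synthetic study below
the matcher-only ranking sits barely above random, and mixing it in at
α = 0.3 lowers MAP below the BM25 baseline at every tested condition. A
diagnostic that replaces the cosine with the raw dot product of the same
score vectors (preserving magnitude) ranks on par with or above BM25 and
makes the fusion beat the baseline consistently — evidence that the
filters carry real signal and the scale-invariance of the cosine over
collapsed representations is the sole bottleneck. We keep the
architecture as designed and report the behaviour as measured; a trained
fully connected layer (which this model deliberately omits) would be the
principled escape from the collapse.

## The synthetic collection generator

The generator emulates, at desk scale, a caption-indexed image collection
whose relevance is driven by semantic concept overlap:

* **Documents** (default 500): 2–6 MDF values plus 5–15 filler tokens
  from a 200-word synthetic lexicon, both Zipf-distributed (exponent 1.0)
  — a few modalities dominate captions, a few stopword-like fillers
  dominate prose. Captions are topically coherent: a fraction
  (`category_coherence = 0.7`) of the sampling mass is focused on one
  facet per document, so semantically close features co-occur — the
  structure the co-occurrence and PMI filters assume. Each feature
  mention is written as a uniformly chosen surface form (canonical string
  or synonym), so "MRI" and "Magnetic Resonance Imaging" refer to the
  same concept but share no tokens: the lexical gap concept annotation
  bridges and token matching cannot.
* **Queries** (default 20): 1–3 MDF values drawn uniformly over the
  catalogue (topic sets span the vocabulary rather than mirroring caption
  frequencies) plus 0–2 filler tokens.
* **Relevance**: rel(q, d) = 1 iff the mean over query features of the
  best semantic similarity to any document feature reaches τ = 0.6, then
  flipped with probability ε = 0.05 (imperfect assessments). Best-match
  overlap (not full bipartite matching) keeps relevance monotone in the
  document's feature set and cheap to compute. Typical density is ~13% of
  all (query, document) pairs — denser than a production-scale
  collection, a consequence of the small corpus and the 87-value
  catalogue.

Generation is a pure function of (config, seed); identical inputs yield
byte-identical corpus/query/qrels files. What the generator does *not*
model: running prose (fillers are i.i.d. tokens, not language),
misspellings or uncatalogued synonyms, graded relevance, and any
dependence of relevance on the non-MDF text. Passing tests on this
generator therefore demonstrate correctness and determinism of the
pipeline and the direction of the fusion trade-off, not performance on
real caption collections.

## Numerical and procedural choices

* Problem sizes: the improvement study uses 20 replicates of the default
  500-document collection; end-to-end checks in the test suite use 60–120
  document collections, which exercise every code path at a few seconds
  per run.
* The re-rank depth defaults to 1000 (TREC convention), which on the
  default collection means every document with a positive BM25 score is
  re-scored.
* Matrix round-trips use 17-significant-digit TSV and pandas'
  `float_precision="round_trip"` parser so save/load is bit-identical.
* The organization factor γ tests whether the query's features, in
  first-occurrence order, form a subsequence of the document's occurrence
  list; repeated query mentions are ignored.
* The feature-difference query filter defaults to the inverse count of
  *missing* query features; the alternative inverse-overlap variant is
  available as `fdqf_variant="intersection"`.
* Empty baselines, queries or documents never raise inside the pipeline:
  filters return 0, the matcher returns 0 for empty representations, and
  fusion of an empty candidate list is an empty list.

## Known limitations

* The annotator is a dictionary matcher; concepts absent from the
  catalogue (or spelled unexpectedly) are invisible to the semantic
  pipeline and only reachable through the BM25 term channel.
* The untrained network's cosine collapse (above) makes the matcher-only
  ranking weak; on the synthetic collections the fused score at α = 0.3
  does not improve on the BM25 baseline, although it always improves on
  the matcher-only limit.
* Corpus statistics are document-level presence counts; windowed
  co-occurrence is not implemented.
* Only binary relevance metrics are provided (no nDCG/bpref).
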