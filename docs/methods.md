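# Methods

## Overview

The pipeline turns abstract records into sentence-level spice–disease
relation instances, classifies their polarity, aggregates the results
over a three-level disease hierarchy into spectrum scores and
per-category recommendations, and explains positive associations with
phytochemical paths. Every stage is deterministic given its seed.

## Dictionary construction and ingest

Scientific names are standardized by stripping trailing infraspecific
qualifiers (`var.`, `subsp.`, `ssp.`, `cv.`, `f.`); the binomial is
kept unchanged otherwise. English plurals are added by rule: `+es`
after `ss/x/z/ch/sh`, `-y → -ies` after a consonant, plain `+s`
otherwise; a name already ending in a lone `s` is treated as plural
and left alone, which makes the expansion idempotent. Common names
appearing under more than one species are removed from all of them —
after that the surface → species map is a function — and a species
whose common names empty out remains matchable through its scientific
name. All matchable surfaces are lowercased at build time: the source
prose mixes sentence case, title case and Latin binomials, and
case-insensitive matching maximizes recall at negligible ambiguity
cost for this vocabulary.

MEDLINE-dialect XML is parsed with lxml. Citations without abstract
text are dropped (counted and logged), citations without a PMID are
skipped with a warning, and multi-part `AbstractText` sections are
joined with single spaces. Dates are retained as years.

## Named entity recognition

Both entity types use dictionary matching over *token* sequences with
greedy leftmost-longest semantics: at each position the longest
surface starting there is emitted and scanning resumes after its last
token, so same-type mentions never overlap and ties cannot arise (one
token span identifies one pattern; across positions, leftmost wins).
The matcher is a trie over token sequences built in time linear in the
total surface tokens. Disease tagging uses the same machinery over
ontology term names as a bundled fallback; output of an external
statistical disease tagger can be supplied instead through an adapter
that converts character spans to token spans and drops records whose
identifiers do not resolve.

## Preprocessing and candidate construction

Sentence segmentation is rule-based (`. ! ?` followed by whitespace,
with an abbreviation stop list); part-of-speech and chunk tags come
from a pluggable tagger contract whose bundled default uses suffix
heuristics and small closed-class lists. Both are deliberately simple:
the downstream contract (one tag per token, two layers) is what
matters, and tests must run without model downloads. Normalization
removes every character outside letters/digits/whitespace/`! , . : ;`,
keeps the retained punctuation as single tokens, lowercases, and
replaces integers and decimals with a reserved `NUM` token. Reserved
tokens (`NUM`, `SPICE`, `DISEASE`, `MASKED`) pass through unchanged,
making normalization idempotent.

A sentence is a candidate iff it contains at least one spice and one
disease mention. It is duplicated once per (spice, disease) mention
pair; the focal spice span collapses to a single `SPICE` token, the
focal disease to `DISEASE`, and every non-focal entity mention to
`MASKED` (masking with a placeholder rather than deletion preserves
the relative positions of all non-entity tokens across the instances
of one sentence). Signed token distances to the focal pair are
attached so left and right context stay distinguishable.

## Relation model

Features are unigram+bigram counts scaled by `idf(t) = log(N / n_t)`
(natural log, unsmoothed), computed directly so a term present in
every sentence carries exactly zero weight. The engine is a one-vs-all
linear SVM (scikit-learn `LinearSVC`, `C` exposed, default 1.0,
seeded): three binary separators, prediction by argmax of decision
values. A convolutional sentence classifier with word/position/PoS/
chunk embedding channels is a recognized alternative engine for this
task; it is not implemented here, and the SVM is the default and only
engine.

Class imbalance is handled by oversampling inside training folds only:
a class of size *m* with factor *f* grows to `round(m·f)` via whole
duplication plus a seeded sample without replacement for the
fractional remainder. Default factors are 12 for the negative class
and 1.35 for the positive class, mirroring the imbalance of an
annotated corpus with class counts 2669/301/3742
(positive/negative/neutral). Cross-validation is stratified k-fold
(default k = 5) with oversampling applied after the split, so
duplicates never straddle a train/validation boundary; hyperparameters
are selected by mean validation macro-F1.

Evaluation reports per-class precision, recall and F1 from one-vs-rest
confusion tables, overall accuracy, and unweighted macro averages;
0/0 ratios are reported as 0 with a warning. Predicted negative
associations pass through a manual-review hook (confirm/reject per
instance) before scoring; with no override file all predictions are
accepted and a notice is logged.

## Hierarchy rollup and spectrum scores

Tree numbers deeper than three segments are truncated to their
three-segment ancestor, so a depth-5 ontology scores identically to
its depth-3 truncation. Presence is binary at every level — evidence
counts never change a score — and a pair carrying both polarities
contributes to both Ω⁺ and Ω⁻, which are computed independently.

Degenerate cases: a category with zero sub-categories (or a
sub-category with zero level-3 diseases) contributes nothing and is
excluded from the corresponding presence count, with a log message. A
disease whose deepest tree number is level ≤ 2 counts toward
category/sub-category presence but not the level-3 sums. The number of
categories *D* is always taken from the loaded ontology, never
hard-coded.

In the category-restricted score Ωᵢ = d̂ˢᵢ · Σ_k α̂ˢ_k / α_k, α̂ˢ_k is
the number of *associated level-3 diseases* within sub-category k
(with α_k the sub-category's total disease count) — the reading
consistent with the global score's structure and its (dᵢ)² bound.

Recommendations rank spices per category by tradeoff ΔΩᵢ descending,
ties broken by Ωᵢ⁺ descending and then spice id; spices with
ΔΩᵢ ≤ 0 are flagged as having no net benefit.

## Tripartite explanation

Compound tables are filtered to bioactive compounds and therapeutic
links; an association (s, d) is explained iff some remaining compound
is both contained in the spice and linked to the same disease
identifier (join on normalized ontology IDs, never on names). Coverage
counts distinct (spice, disease) pairs, restricted to rows resolvable
at level 3 when an ontology is supplied; explained rows and the
hypotheses list partition the positive rows.

## Synthetic data generator

The generator emulates the statistical structure of the real study
inputs while keeping ground truth exact:

- **Ontology**: `n_categories` (default 27, matching the MeSH disease
  branch) × 2–6 sub-categories × 2–5 diseases, every node carrying one
  dotted tree number. Names are pseudo-words with medical suffixes;
  about 30 % of leaves get a two-word form to exercise multi-token
  matching.
- **Lexicon**: default 24 species with 1–3 synonyms plus a planted
  plural and, for the second species, a planted multi-word synonym
  containing the first species' name as a token (longest-match test
  case). Disease and spice pseudo-words draw on disjoint syllable
  pools, so surfaces can never collide across entity types.
- **Corpus**: default 200 abstracts of 3–8 sentences, each sentence
  built from a fixed template bank keyed to its class, with one spice
  surface and one disease leaf name per sentence. Cue words are
  disjoint across the three banks, so the noiseless corpus has a
  Bayes-optimal ceiling of 1 — by design, since recovery tests need a
  known ceiling. Default label priors are 2669/6712, 301/6712,
  3742/6712 (the annotated-corpus composition); label noise flips the
  *recorded* label uniformly to a different class while the sentence
  text keeps its template, the simplest symmetric corruption.
- **Planted spectrum profiles** choose which (category, sub-category)
  cells a spice's positive (or negative) sentences cover; profile
  sentences are appended as dedicated abstracts and exempt from label
  noise so ranking-recovery tests are exact.
- **Phytochemical tables**: exactly `round(explainable_fraction ×
  n_pairs)` positive pairs (default fraction 0.37) receive a
  spice → bioactive compound → therapeutic-link path; every other pair
  receives a decoy compound whose path is broken in exactly one place
  (non-bioactive, or a marker/inferred link), so the filters are
  exercised but no unplanned explanation can occur. The default
  bioactive flag rate is 570/866, the composition of a curated
  compound table.

What the generator does **not** emulate: realistic biomedical prose
(hedging, coordination, anaphora, abbreviations), mention boundary
ambiguity, cross-sentence relations, polysemous surfaces shared
between spices and diseases, and MEDLINE metadata beyond the fields
the ingest stage reads. Passing tests therefore demonstrate that the
pipeline machinery is correct under known conditions — exact entity
recovery, classifier recovery of separable signal, exact score and
coverage arithmetic — not that real-literature accuracy would match.

## Numerical and design choices

- TF-IDF uses an unsmoothed natural-log idf computed in-house; library
  TF-IDF implementations add smoothing or a `+1` shift, which changes
  the "ubiquitous term has zero weight" property.
- Fractional oversampling rounds the class total with `round()` and
  samples the remainder without replacement, seeded.
- The SVM regularization constant and TF-IDF variants are exposed in
  the API with plain defaults (`C = 1.0`, raw counts, no norm).
- Early-stopping-style validation splits are not needed for the SVM
  engine; cross-validation uses stratified folds with a fixed seed.
- Test problem sizes: ~1 000 candidate instances (200 abstracts) for
  classifier recovery, 1 000 random sentences for the tagger oracle
  check, 25–40 random tables for score invariants — sizes at which
  every statistical assertion in the suite is stable across seeds and
  the whole suite runs in seconds.

## Known limitations

- The bundled PoS/chunk tagger is heuristic; swap in a real tagger
  through the `LinguisticTagger` contract for linguistic fidelity.
- The dictionary disease tagger cannot resolve surface variants absent
  from the ontology's name list; use the external-tagger adapter for
  real corpora.
- Evidence counts are tracked but deliberately ignored by the scores;
  no dose, potency or study-quality weighting is attempted.
- Negative-association cleaning is a hook, not a model: real use
  expects a manual review file.
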