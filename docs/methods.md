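# Methods

## Problem and approach

Grounding maps an entity string, optionally accompanied by surrounding
text and an organism preference, to ranked candidate identifiers.
The method is *exact lookup over generated variants*: rather than
searching the lexicon fuzzily (edit distance), the engine enumerates
the orthographic forms under which the input could plausibly appear in
a curated resource, and looks each up exactly in a hash map keyed by
canonicalized term text. This keeps per-query cost independent of
lexicon size and makes the candidate set fully auditable: a term is a
candidate if and only if its canonical text equals one of the variants.

## Canonicalization

Index keys and variants are canonicalized: Unicode NFC, micro sign
folded to Greek mu and final sigma to sigma, lowercased, dash-like
characters (hyphen, en/em dash, minus, underscore, …) replaced by
spaces, whitespace collapsed, stripped. Canonicalization is idempotent,
and every `Term` stores `canonical == canonicalize(text)` as an
invariant.

## Variant generation

For an input string the engine emits, deduplicated and in
deterministic order:

1. the canonical (separator-as-space) form;
2. the separator-removed (joined) form;
3. if a token is, or ends with, a spelled-out Greek name: the joined
   form with the name replaced by the Greek letter, and by its single
   Latin initial (`PKC-Delta` → `pkcδ`, `pkcd`). Contracted elements
   attach to the preceding token, so no spaced forms are emitted here;
4. if a token contains a Greek letter: the spelled-out-name form both
   spaced and joined, and the joined initial form (`IFN-γ` →
   `ifn gamma`, `ifngamma`, `ifng`).

One token per expansion round is substituted (the first Greek-bearing
one), bounding combinatorics. At lookup time, de-pluralized forms of
each variant (trailing `s` dropped when the stem keeps ≥ 3 characters
and the word does not end in `ss`; `-ies` → `-y`) are also looked up,
so plural mentions can match singular terms; such matches carry a
`plural_dropped` feature and are penalized.

## String comparison and scoring

Candidates are scored by comparing the *original* (un-canonicalized)
query with the matched term's stored text. Both are segmented into
runs (title-case, uppercase, lowercase, digits, single Greek letters),
each segment tagged with whether an explicit separator preceded it,
and the two segment lists are aligned greedily: case-insensitive
equality, Greek equivalence (name ↔ letter ↔ initial, compared by
first-character case), or prefix-splitting of one side (so `PKCD`
aligns against `PKC` + `Delta` as `PKC` + `D`). The features are the
count of separator mismatches at aligned boundaries, a per-segment
capitalization profile, and the plural flag; strings no variant
relationship can align receive a generic penalty.

The score is `similarity × status`, both in (0, 1]:

| constant | value |
|---|---|
| status: standard_name | 1.0 |
| status: curated | 0.99858675 |
| status: synonym | 0.99 |
| status: former_name | 0.95 |
| penalty per separator mismatch | 0.998 |
| penalty per capitalization mismatch (either direction) | 0.997 |
| penalty per mixed-case mismatch | 0.99 |
| plural penalty | 0.995 |
| unaligned penalty | 0.9 |

The constants live in `src/bioground/data/scoring.json` and were fixed
once, subject to the ordering constraints the model must satisfy: an
exact standard-name match scores exactly 1.0; each status rank is
strictly below the previous; every feature strictly lowers the score;
and a one-step status downgrade outweighs a one-step similarity
difference, so `PKC-Delta` → `PKCD` (better string match, synonym
status, 0.998 × 0.99 = 0.98802) ranks below `PKCdelta` (curated,
0.998 × 0.997 × 0.99858675 ≈ 0.9936). The curated multiplier is the
one calibrated value, chosen so the PKC-Delta fixture surfaces 0.9936
and the calibration is locked in as a regression test.

Per entity (namespace, identifier) only the best-scoring candidate
survives; ties break deterministically by (status rank, fewer feature
mismatches, source, namespace, identifier, term text) — the last key
is why `PKCdelta` rather than the equally scored `PKCδ` is surfaced.

## Disambiguation models

One classifier per ambiguous string, under one-sense-per-discourse:
each training document carries a single sense label. Features are
tf-idf weighted unigrams + bigrams; tokens are lowercased word
characters of length ≥ 2, idf = ln((1+N)/(1+df)) + 1, L2 row
normalization (fitted with scikit-learn's vectorizer, which implements
exactly this convention). The classifier is an L2-regularized
multinomial logistic regression (C = 1.0, lbfgs, deterministic given
the seed). Generalization is estimated by stratified 5-fold
cross-validation — the vocabulary refitted within each fold on the
training split to avoid leakage — scored by macro-averaged F1
(unweighted mean of per-class F1 over classes with support in the
truth; a class with no true positives contributes 0). Models with mean
CV macro-F1 below 0.7 are excluded from deployment.

Fitted models are stored self-contained (vocabulary, idf vector,
per-sense coefficient matrix and intercepts; the two-class sklearn
form is expanded to per-sense softmax rows), serialized as a JSON
bundle that round-trips bit-identically, with prediction implemented
in-package — so deployment does not depend on the training library's
internals.

Given context, sense probabilities adjust match scores as
`adjusted = score × (ε + (1 − ε)·P(sense))` with ε = 0.05: monotone in
both inputs, bounded in [0, 1], and a probability of 1 leaves the
string score essentially untouched while near-zero probabilities
suppress the match without deleting it. Without context, or without a
model for the string, scores are untouched — no corpus-frequency prior
is applied.

## Species prioritization

An ordered taxonomy-id list reranks matches only within groups of
scores equal to within 1e-9: the priority expresses preference, not
evidence, so it never overrides a strictly better string match. The
reranking is a stable permutation (scores untouched, unannotated
matches keep their relative order, idempotent). A priority can be
derived from MeSH annotations via a packaged descriptor → taxonomy
table covering 16 common model organisms; the table is a two-column
TSV and user-extensible.

## Synthetic data

The fixtures module generates the inputs all tests run on:

* **Lexicons** — entities with one standard name and 1–4 synonyms of
  random gene-symbol-like strings, unique in canonical form by
  construction; a controlled number of synonym texts
  (`round(ambiguity_rate × n_entities)`, each attached to a second
  entity) is the only source of ambiguity; a configurable fraction of
  synonyms carries a Greek element.
* **Labeled corpora** — documents are bags of words drawn from
  per-sense Zipf-weighted vocabularies (exponent 1.1) with a
  configurable shared fraction: 0 makes senses perfectly separable,
  1 makes text independent of the label. Defaults are 2 senses ×
  100 documents × 50-word vocabularies × 50-word documents.

Both are pure functions of their spec including the seed. They emulate
the *structure* that matters to the machinery — synonym collisions,
Greek orthography, separable vs. uninformative context — but not real
nomenclature or biomedical prose: passing tests demonstrate that the
algorithms behave as specified under known conditions, not that any
particular real-world accuracy is achieved. Benchmarking against
curated corpora (e.g. BioCreative-style datasets) is what the
evaluation harness is for; those corpora are external inputs and are
not shipped.

The shipped hand-written fixtures are the PKC-Delta term set (three
lexicalizations of HGNC:9399 with differing statuses plus a MAP2K1
standard-name distractor) and a DAP4-style two-gene shared-synonym
fixture.

## Numerical and design choices

* Scores are IEEE doubles; "equal" scores in species reranking means
  within 1e-9.
* The evaluation harness counts precision over records with ≥ 1
  returned match and recall over all records, identically under the
  strict (top-ranked hit) and permissive (any-rank hit) conditions;
  F1 is the harmonic mean. Matches in namespaces absent from a
  supplied equivalence map count as misses.
* Gene/protein merging is on by default (synonym usage in text rarely
  distinguishes them); merged terms keep their original
  namespace/identifier in the mapped-from fields. The merge keeps the
  protein term's standard name, since the mapping table carries
  identifiers only.
* OBO ingestion maps the stanza name to a standard_name term and EXACT
  synonyms to synonym status by default; other scopes are skipped
  unless configured, and obsolete stanzas are skipped unless
  `keep_obsolete` turns them into former_name terms.
* Duplicate terms are preserved by the loaders (faithful to source
  files) and collapsed at index build, where they are counted in the
  build report.
* When identical (entity, text) pairs arrive with different statuses
  from different sources, both are indexed and the status ordering in
  scoring decides which surfaces.
* Test problem sizes: oracle-equivalence checks use 100 random
  lexicons of ≤ ~200 terms × 50 queries; score-bound fuzzing uses 10⁴
  random strings; sense-recovery uses 2- and 3-sense corpora at 100
  documents per sense; the context-flip check uses 200 fresh contexts
  per sense.

## Known limitations

* Term texts containing tabs or newlines cannot be represented in the
  TSV term table.
* Variant generation substitutes one Greek element per round; strings
  with several Greek elements are only partially expanded.
* The plural heuristic is a suffix rule; irregular plurals are not
  recognized.
* Disambiguation needs context text; there is no interaction-based or
  frequency-prior fallback, and acronym-definition patterns are not
  modeled.
* The REST service uses the reference WSGI server — fine for local and
  test use, not hardened for production traffic.
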