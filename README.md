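# bioground

Biomedical named-entity normalization ("grounding"): map a free-text
entity string — a gene symbol, protein name, small molecule, biological
process, disease — to a namespace and identifier in a curated resource
(e.g. `JNK-1` → HGNC:6881), with a score expressing how good the match
is.

It is aimed at text-mining and curation pipelines, interactive search
boxes, and modelers who need identifiers for informally named concepts.
The package provides a Python library, a `bioground` command-line tool,
and a small REST service.

## How it works

**Scored string matching.** Every name and synonym in the lexicon is
stored as a *term* (namespace, identifier, text, status, canonical
text, standard name, source, optional mapped-from ids, optional
organism) and indexed in a hash map keyed by canonicalized text, so
candidate lookup is O(1) on average in the lexicon size. For an input
string the engine generates orthographic variants — separator handling
plus Greek-letter spell-out, substitution and contraction (for
`PKC-Delta`: `pkc delta`, `pkcd`, `pkcdelta`, `pkcδ`) — looks each up
exactly, and scores every hit by comparing the *original* string with
the matched term's stored text. The score is

```
score = similarity(query, term_text) × status(term)   ∈ [0, 1]
```

where the similarity component multiplies penalties for space/dash
mismatches, capitalization differences and plural markers, and the
status component ranks standard name > curated > synonym > former name.
An exact match of a standard name scores exactly 1.0. Only the best
match per entity is surfaced.

**Context-aware disambiguation.** Shared synonyms (e.g. `DAP4`, a
synonym of both DLGAP4 and THAP12) get identical string scores. Under
the one-sense-per-discourse assumption the package trains one logistic
regression per ambiguous string over tf-idf weighted unigrams and
bigrams of the surrounding document; models are screened by stratified
5-fold cross-validated macro-F1 (deployment cutoff 0.7). When context
text accompanies a query, the sense probabilities rescale the match
scores.

**Species prioritization.** An ordered organism preference list
(taxonomy ids, optionally derived from a publication's MeSH
annotations) breaks ties among equally scored cross-species
gene/protein matches without altering scores.

## Worked example

```sh
bioground fixtures --out-dir fx
bioground ground "PKC-Delta" --terms fx/pkc_terms.tsv
```

prints

```json
[
 {
  "score": 0.9935998077704999,
  "term": {
   "id": "9399",
   "namespace": "HGNC",
   "organism": "9606",
   "standard_name": "PRKCD",
   "status": "curated",
   "text": "PKCdelta"
  },
  "variant_used": "pkcdelta"
 }
]
```

The input generated four variants; three of them hit terms (`PKCD`,
`PKCdelta`, `PKCδ`), all lexicalizations of the human gene HGNC:9399
(PRKCD). `PKCD` is the best *string* match — its capitalized suffix
`D` agrees with the input's `Delta` — but it is a plain synonym, and
the status component drops it below the curated `PKCdelta`, which
surfaces with score 0.9936 (rounded). A single match is returned
because all three candidates ground the same entity.

The same result is available in Python:

```python
from bioground import build_index, ground
from bioground.fixtures import pkc_fixture

matches = ground(build_index(pkc_fixture()), "PKC-Delta")
print(matches[0].entity, round(matches[0].score, 4))   # ('HGNC', '9399') 0.9936
```

and over HTTP (`bioground serve --terms fx/pkc_terms.tsv`, then POST
`{"text": "PKC-Delta"}` to `/ground`) with byte-identical JSON.

Other CLI commands: `index-build` (validate a term table, emit index
statistics), `train-disamb` (fit a sense classifier from a JSONL
labeled corpus), `evaluate` (top/any precision–recall harness),
`serve`.

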