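"""Synthetic lexicons and labeled corpora for testing and calibration.

Real grounding resources are millions of strings harvested from curated
databases, and real disambiguation corpora are labeled PubMed articles;
neither is needed to exercise the machinery.  This module generates

* synthetic lexicons with a controlled amount of synonym ambiguity and
  Greek-letter content (:func:`generate_lexicon`),
* synthetic labeled corpora where documents are bags of words drawn
  from per-sense Zipf-weighted vocabularies with a controlled shared
  fraction (:func:`generate_ambiguous_corpus`),

plus two small hand-written fixtures: the PKC-Delta term set (one
entity under three synonyms of differing status, with a distractor
standard name) and a two-gene DAP4-style ambiguity fixture.

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .disambiguation import LabeledCorpus, LabeledDocument
from .greek import GREEK_NAME_TO_LETTER
from .lexicon import Term, TermStatus
from .stringmatch import canonicalize

__all__ = [
    "pkc_fixture",
    "dap4_fixture",
    "SyntheticLexiconSpec",
    "generate_lexicon",
    "SyntheticCorpusSpec",
    "generate_ambiguous_corpus",
]


def pkc_fixture() -> list[Term]:
    """The protein-kinase-C-delta term set.

    Three lexicalizations of the human gene HGNC:9399 (standard symbol
    PRKCD) — "PKCD" with synonym status, "PKCdelta" and "PKCδ" with
    curated status — plus an unrelated standard-name distractor,
    MAP2K1.  Grounding "PKC-Delta" against this fixture exercises the
    full variant/scoring/deduplication path.
    """
    prkcd = dict(
        namespace="HGNC",
        identifier="9399",
        standard_name="PRKCD",
        source="hgnc",
        organism="9606",
    )
    return [
        Term(text="PKCD", status=TermStatus.SYNONYM, **prkcd),
        Term(text="PKCdelta", status=TermStatus.CURATED, **prkcd),
        Term(text="PKCδ", status=TermStatus.CURATED, **prkcd),
        Term(
            namespace="HGNC",
            identifier="6840",
            text="MAP2K1",
            status=TermStatus.STANDARD_NAME,
            standard_name="MAP2K1",
            source="hgnc",
            organism="9606",
        ),
    ]


def dap4_fixture() -> list[Term]:
    """Two human genes sharing the synonym "DAP4".

    DLGAP4 (HGNC:24476) and THAP12 (HGNC:16958) both carry "DAP4" as a
    plain synonym, so string matching alone cannot rank them apart —
    the canonical setting for context-based disambiguation.
    """
    return [
        Term(
            namespace="HGNC", identifier="24476", text="DLGAP4",
            status=TermStatus.STANDARD_NAME, standard_name="DLGAP4",
            source="hgnc", organism="9606",
        ),
        Term(
            namespace="HGNC", identifier="24476", text="DAP4",
            status=TermStatus.SYNONYM, standard_name="DLGAP4",
            source="hgnc", organism="9606",
        ),
        Term(
            namespace="HGNC", identifier="16958", text="THAP12",
            status=TermStatus.STANDARD_NAME, standard_name="THAP12",
            source="hgnc", organism="9606",
        ),
        Term(
            namespace="HGNC", identifier="16958", text="DAP4",
            status=TermStatus.SYNONYM, standard_name="THAP12",
            source="hgnc", organism="9606",
        ),
    ]


# ---------------------------------------------------------------------------
# synthetic lexicons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticLexiconSpec:
    """Parameters of a synthetic lexicon.

    ambiguity_rate is the number of deliberately shared synonym texts
    per entity (each shared text is attached to two distinct entities);
    greek_rate is the fraction of synonyms carrying a Greek element.
    """

    n_entities: int = 100
    synonyms_per_entity: tuple[int, int] = (1, 4)
    ambiguity_rate: float = 0.1
    greek_rate: float = 0.1
    organism_pool: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError("ambiguity_rate must be in [0, 1]")
        if not 0.0 <= self.greek_rate <= 1.0:
            raise ValueError("greek_rate must be in [0, 1]")
        if self.n_entities < 1:
            raise ValueError("n_entities must be positive")
        if self.ambiguity_rate > 0 and self.n_entities < 2:
            raise ValueError("ambiguity requires at least two entities")
        lo, hi = self.synonyms_per_entity
        if lo < 0 or hi < lo:
            raise ValueError("synonyms_per_entity must be a (lo, hi) range")


_GREEK_NAMES = sorted(GREEK_NAME_TO_LETTER)
_LETTERS = np.array(list(string.ascii_uppercase))
_DIGITS = np.array(list(string.digits))


def _random_symbol(rng: np.random.Generator, used: set[str]) -> str:
    """A gene-symbol-like random string, unique in canonical form."""
    while True:
        n_letters = int(rng.integers(3, 7))
        body = "".join(rng.choice(_LETTERS, size=n_letters))
        if rng.random() < 0.7:
            body += str(rng.integers(1, 100))
        if canonicalize(body) not in used:
            used.add(canonicalize(body))
            return body


def generate_lexicon(spec: SyntheticLexiconSpec) -> list[Term]:
    """Generate a synthetic lexicon realizing the spec.

    Each entity gets one standard-name term and a random number of
    synonym terms; a ``round(ambiguity_rate * n_entities)`` subset of
    synonym texts is additionally attached to a second, distinct entity,
    which is the only source of ambiguity (all other texts are unique by
    construction).  Deterministic given the spec.
    """
    rng = np.random.default_rng(spec.seed)
    used: set[str] = set()
    lo, hi = spec.synonyms_per_entity
    terms: list[Term] = []
    synonym_terms: list[Term] = []
    entity_ids: list[str] = []
    for i in range(spec.n_entities):
        ident = str(1000 + i)
        entity_ids.append(ident)
        organism = (
            str(rng.choice(np.array(spec.organism_pool)))
            if spec.organism_pool
            else None
        )
        standard = _random_symbol(rng, used)
        common = dict(
            namespace="XNS",
            identifier=ident,
            standard_name=standard,
            source="synthetic",
            organism=organism,
        )
        terms.append(Term(text=standard, status=TermStatus.STANDARD_NAME, **common))
        n_syn = int(rng.integers(lo, hi + 1))
        for _ in range(n_syn):
            text = _random_symbol(rng, used)
            if rng.random() < spec.greek_rate:
                greek = _GREEK_NAMES[int(rng.integers(len(_GREEK_NAMES)))]
                text = f"{text}-{greek}"
                used.add(canonicalize(text))
            syn = Term(text=text, status=TermStatus.SYNONYM, **common)
            terms.append(syn)
            synonym_terms.append(syn)

    n_shared = round(spec.ambiguity_rate * spec.n_entities)
    n_shared = min(n_shared, len(synonym_terms))
    if n_shared:
        chosen = rng.choice(len(synonym_terms), size=n_shared, replace=False)
        for idx in chosen:
            donor = synonym_terms[int(idx)]
            others = [e for e in entity_ids if e != donor.identifier]
            target = others[int(rng.integers(len(others)))]
            target_standard = next(
                t.standard_name for t in terms if t.identifier == target
            )
            terms.append(
                Term(
                    namespace="XNS",
                    identifier=target,
                    text=donor.text,
                    status=TermStatus.SYNONYM,
                    standard_name=target_standard,
                    source="synthetic",
                    organism=donor.organism,
                )
            )
    return terms


# ---------------------------------------------------------------------------
# synthetic labeled corpora
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Parameters of a synthetic labeled corpus.

    Documents are bags of words over per-sense vocabularies; a
    ``shared_vocab_fraction`` of each sense's vocabulary is common to
    all senses (1.0 makes text independent of the label, 0.0 makes
    senses perfectly separable).  Word frequencies are Zipf-weighted.
    """

    n_senses: int = 2
    docs_per_sense: int = 100
    vocab_size_per_sense: int = 50
    shared_vocab_fraction: float = 0.0
    doc_length: int = 50
    seed: int = 0
    entity_text: str = "AMB1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_vocab_fraction <= 1.0:
            raise ValueError("shared_vocab_fraction must be in [0, 1]")
        if self.n_senses < 2:
            raise ValueError("need at least two senses")
        if self.vocab_size_per_sense < 1 or self.doc_length < 1:
            raise ValueError("vocabulary and document sizes must be positive")


def generate_ambiguous_corpus(
    spec: SyntheticCorpusSpec,
    senses: Sequence[tuple[str, str]] | None = None,
) -> LabeledCorpus:
    """Generate a labeled corpus realizing the spec.

    Sense labels default to ``("XNS", "S1"), ("XNS", "S2"), ...`` and
    can be overridden (e.g. with real namespace/identifier pairs when
    pairing the corpus with a lexicon fixture).  Deterministic given
    the spec.
    """
    if senses is None:
        senses = [("XNS", f"S{i + 1}") for i in range(spec.n_senses)]
    if len(senses) != spec.n_senses:
        raise ValueError("senses must match n_senses")
    rng = np.random.default_rng(spec.seed)
    n_shared = round(spec.shared_vocab_fraction * spec.vocab_size_per_sense)
    shared = [f"shw{k:04d}" for k in range(n_shared)]
    docs: list[LabeledDocument] = []
    for s, label in enumerate(senses):
        own = [
            f"s{s}w{k:04d}"
            for k in range(spec.vocab_size_per_sense - n_shared)
        ]
        vocab = np.array(shared + own)
        ranks = np.arange(1, len(vocab) + 1, dtype=float)
        weights = 1.0 / ranks**1.1
        weights /= weights.sum()
        for d in range(spec.docs_per_sense):
            words = rng.choice(vocab, size=spec.doc_length, p=weights)
            docs.append(
                LabeledDocument(
                    doc_id=f"s{s}_d{d:04d}",
                    text=" ".join(words),
                    label=tuple(label),
                )
            )
    return LabeledCorpus(entity_text=spec.entity_text, documents=tuple(docs))
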