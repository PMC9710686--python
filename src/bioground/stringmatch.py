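"""Approximate scored string matching.

Grounding an entity string proceeds in four steps:

1. **Variant generation** — orthographic variants of the input are
   produced (separator handling, Greek-letter spell-out/substitution),
   each canonicalized.
2. **Lookup** — every variant is looked up *exactly* in a hash map of
   canonicalized term texts (:class:`bioground.lexicon.GroundingIndex`),
   so lookup cost is independent of lexicon size on average.
3. **Scoring** — the original (un-canonicalized) input is compared with
   each matched term's stored text; the match score is the product of a
   string-similarity component (separator, capitalization and plural
   features) and a status component (standard name > curated > synonym >
   former name).  Scores lie in [0, 1], with 1.0 reserved for an exact
   match of a standard name.
4. **Ranking** — matches are deduplicated per entity (only the best
   match for each namespace/identifier survives), optionally adjusted by
   a context-based disambiguation model and a species priority list, and
   returned sorted by score.

There is deliberately no edit-distance fuzziness: a string either
collides with a term under some generated variant or it does not.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .config import DEFAULT_SCORING, ScoringConfig
from .greek import (
    GREEK_LETTER_TO_NAME,
    GREEK_NAME_TO_INITIAL,
    GREEK_NAME_TO_LETTER,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .disambiguation import DisambRegistry
    from .lexicon import GroundingIndex, Term

logger = logging.getLogger(__name__)

__all__ = [
    "canonicalize",
    "generate_variants",
    "lookup",
    "compare_strings",
    "score_match",
    "ground",
    "Grounder",
    "MatchFeatures",
    "ScoredMatch",
    "scored_match_to_dict",
]

# dash-like separators folded to a space by canonicalization
_DASH_CHARS = "-‐‑‒–—―−_"
_DASH_RE = re.compile(f"[{re.escape(_DASH_CHARS)}]+")
_SEP_SPLIT_RE = re.compile(f"[\\s{re.escape(_DASH_CHARS)}]+")
_WS_RE = re.compile(r"\s+")

# single-character folds applied before lowercasing: micro sign -> Greek mu,
# final sigma -> sigma
_CHAR_FOLD = str.maketrans({"µ": "μ", "ς": "σ"})

_GREEK_CHARS = "".join(GREEK_LETTER_TO_NAME)
_GREEK_RE = re.compile(f"[{_GREEK_CHARS}]")

# segmentation for string comparison: title-case run, uppercase run,
# lowercase run, digit run, single Greek letter (either case), anything else
_SEGMENT_RE = re.compile(
    r"[A-Z][a-z]+|[A-Z]+|[a-z]+|\d+|[Α-Ωα-ωµ]|\S"
)


def canonicalize(text: str) -> str:
    """Return the canonical form of ``text`` used as the index key.

    Unicode NFC; micro sign folded to Greek mu and final sigma to sigma;
    lowercased; dash-like characters replaced by spaces; whitespace runs
    collapsed to single spaces; stripped.  Idempotent.
    """
    if not text or not text.strip():
        raise ValueError("cannot canonicalize an empty or whitespace-only string")
    s = unicodedata.normalize("NFC", text)
    s = s.translate(_CHAR_FOLD)
    s = s.lower()
    s = _DASH_RE.sub(" ", s)
    s = _WS_RE.sub(" ", s).strip()
    if not s:
        raise ValueError(f"string {text!r} canonicalizes to the empty string")
    return s


def _substitute_token(tokens: list[str], index: int, replacement: str) -> list[str]:
    out = list(tokens)
    out[index] = replacement
    return out


def generate_variants(text: str) -> list[str]:
    """Generate the canonicalized lookup variants of ``text``.

    Always includes the canonical (separator-as-space) form and, when
    the input contains separators, the separator-removed form.  Greek
    elements are expanded in both directions:

    * a spelled-out Greek name is replaced by the Greek letter and by
      its single Latin initial — in the separator-removed form, since
      the contracted element attaches to the preceding token
      (``PKC-Delta`` -> ``pkcδ``, ``pkcd``);
    * a Greek letter is replaced by its spelled-out name in both the
      spaced and the joined form, and by its Latin initial in the
      joined form (``IFN-γ`` -> ``ifn gamma``, ``ifngamma``, ``ifng``).

    At most one token per expansion round is substituted (the first
    Greek-bearing token), which bounds the combinatorics.  The result is
    unique, order-deterministic, and every element is canonical.
    """
    canon = canonicalize(text)
    tokens = canon.split(" ")
    joined = "".join(tokens)

    variants: list[str] = [canon]
    if joined != canon:
        variants.append(joined)

    # Greek name present as a token or a token suffix -> letter / initial
    for i, tok in enumerate(tokens):
        sub = _greek_name_substitutions(tok)
        if sub is None:
            continue
        letter_form, initial_form = sub
        variants.append("".join(_substitute_token(tokens, i, letter_form)))
        variants.append("".join(_substitute_token(tokens, i, initial_form)))
        break

    # Greek letter present -> spelled-out name (spaced + joined) / initial
    for i, tok in enumerate(tokens):
        m = _GREEK_RE.search(tok)
        if m is None:
            continue
        letter = m.group(0)
        name = GREEK_LETTER_TO_NAME[letter]
        named_tok = tok.replace(letter, name, 1)
        initial_tok = tok.replace(letter, name[0], 1)
        named_tokens = _substitute_token(tokens, i, named_tok)
        variants.append(" ".join(named_tokens))
        variants.append("".join(named_tokens))
        variants.append("".join(_substitute_token(tokens, i, initial_tok)))
        break

    unique: list[str] = []
    for v in variants:
        if v and v not in unique:
            unique.append(v)
    return unique


def _greek_name_substitutions(token: str) -> tuple[str, str] | None:
    """If ``token`` is, or ends with, a spelled-out Greek name, return the
    token with the name replaced by (letter, initial)."""
    for name, letter in GREEK_NAME_TO_LETTER.items():
        if token == name or (token.endswith(name) and len(token) > len(name)):
            stem = token[: len(token) - len(name)]
            return stem + letter, stem + GREEK_NAME_TO_INITIAL[name]
    return None


def depluralize(canonical: str) -> str | None:
    """Return the de-pluralized form of a canonical string, or None.

    Trailing ``s`` is dropped when the stem keeps length >= 3 and the
    string does not end in ``ss``; ``-ies`` maps to ``-y``.
    """
    if canonical.endswith("ies") and len(canonical) > 3:
        return canonical[:-3] + "y"
    if canonical.endswith("s") and not canonical.endswith("ss"):
        stem = canonical[:-1]
        if len(stem.replace(" ", "")) >= 3:
            return stem
    return None


def lookup(
    index: "GroundingIndex", variants: Sequence[str]
) -> list[tuple["Term", str]]:
    """Exact canonical-key lookup of each variant in the index.

    Returns the pre-deduplication candidate list: a term hit by several
    variants appears once per variant, in variant order then index
    order.
    """
    hits: list[tuple["Term", str]] = []
    for variant in variants:
        for term in index.lookup(variant):
            hits.append((term, variant))
    return hits


# ---------------------------------------------------------------------------
# string comparison
# ---------------------------------------------------------------------------

#: cap-profile comparison outcomes per aligned segment pair
CAP_SAME = "same"
CAP_QUERY_UPPER_REF_LOWER = "query_upper_ref_lower"
CAP_QUERY_LOWER_REF_UPPER = "query_lower_ref_upper"
CAP_MIXED = "mixed"


@dataclass(frozen=True)
class MatchFeatures:
    """Features of comparing an original query string with a term text."""

    query: str
    ref: str
    exact: bool
    space_dash_mismatch: int
    cap_profile: tuple[str, ...]
    plural_dropped: bool
    aligned: bool = True

    def mismatch_count(self) -> int:
        """Total number of non-clean feature observations (tie-break key)."""
        caps = sum(1 for c in self.cap_profile if c != CAP_SAME)
        return (
            self.space_dash_mismatch
            + caps
            + int(self.plural_dropped)
            + (0 if self.aligned else 1)
        )


@dataclass
class ScoredMatch:
    """One candidate grounding: a term, its score, and diagnostics."""

    term: "Term"
    score: float
    features: MatchFeatures
    variant_used: str
    disamb_probability: float | None = None

    @property
    def entity(self) -> tuple[str, str]:
        return (self.term.namespace, self.term.identifier)


def _prepare(text: str) -> str:
    s = unicodedata.normalize("NFC", text)
    return s.translate(_CHAR_FOLD)


def _segments(text: str) -> list[tuple[str, bool]]:
    """Split into comparison segments, each tagged with whether an explicit
    separator (space/dash) preceded it."""
    out: list[tuple[str, bool]] = []
    for i, chunk in enumerate(_SEP_SPLIT_RE.split(text)):
        if not chunk:
            continue
        first_in_chunk = True
        for m in _SEGMENT_RE.finditer(chunk):
            preceded = first_in_chunk and len(out) > 0 and i > 0
            out.append((m.group(0), preceded))
            first_in_chunk = False
    return out


def _is_greek(segment: str) -> bool:
    return len(segment) == 1 and segment.lower() in GREEK_LETTER_TO_NAME


def _greek_equivalent(a: str, b: str) -> bool:
    """True when segments denote the same Greek element in different forms."""
    al, bl = a.lower(), b.lower()
    forms_a = _greek_forms(al)
    return bl in forms_a and al != bl


def _greek_forms(seg: str) -> set[str]:
    if seg in GREEK_NAME_TO_LETTER:  # spelled name
        return {GREEK_NAME_TO_LETTER[seg], GREEK_NAME_TO_INITIAL[seg]}
    if seg in GREEK_LETTER_TO_NAME:  # letter
        name = GREEK_LETTER_TO_NAME[seg]
        return {name, name[0]}
    if len(seg) == 1:  # possible initial
        return {
            name
            for name in GREEK_NAME_TO_LETTER
            if name[0] == seg
        } | {
            GREEK_NAME_TO_LETTER[name]
            for name in GREEK_NAME_TO_LETTER
            if name[0] == seg
        }
    return set()


def _first_char_cap(q: str, r: str) -> str:
    qu, ru = q[0].isupper(), r[0].isupper()
    if qu == ru:
        return CAP_SAME
    return CAP_QUERY_UPPER_REF_LOWER if qu else CAP_QUERY_LOWER_REF_UPPER


def _token_cap(q: str, r: str) -> str:
    """Capitalization comparison of two case-insensitively equal segments."""
    if q == r:
        return CAP_SAME
    if q.islower() and not r.islower():
        return CAP_QUERY_LOWER_REF_UPPER
    if r.islower() and not q.islower():
        return CAP_QUERY_UPPER_REF_LOWER
    return CAP_MIXED


def _align(
    qsegs: list[tuple[str, bool]], rsegs: list[tuple[str, bool]]
) -> tuple[int, list[str]] | None:
    """Greedy alignment of query segments against reference segments.

    Returns (space_dash_mismatch, cap_profile) or None when the two
    strings cannot be aligned (no variant relationship explains them).
    Segments are aligned by case-insensitive equality, by Greek
    equivalence (name <-> letter <-> initial), or by prefix-splitting
    one side; an inner boundary created by a split carries no separator.
    """
    qs = list(qsegs)
    rs = list(rsegs)
    i = j = 0
    mismatch = 0
    caps: list[str] = []
    while i < len(qs) and j < len(rs):
        (q, qsep), (r, rsep) = qs[i], rs[j]
        if i > 0 and j > 0 and qsep != rsep:
            mismatch += 1
        ql, rl = q.lower(), r.lower()
        if ql == rl:
            caps.append(_token_cap(q, r))
            i += 1
            j += 1
            continue
        if _greek_equivalent(q, r):
            caps.append(_first_char_cap(q, r))
            i += 1
            j += 1
            continue
        if rl.startswith(ql) and len(r) > len(q):
            rs[j] = (r[: len(q)], rsep)
            rs.insert(j + 1, (r[len(q) :], False))
            continue
        if ql.startswith(rl) and len(q) > len(r):
            qs[i] = (q[: len(r)], qsep)
            qs.insert(i + 1, (q[len(r) :], False))
            continue
        # Greek name on one side vs a longer alphabetic run on the other
        # (e.g. query segment "Delta" vs reference segment "Dxx"): try
        # splitting off the initial
        if ql in GREEK_NAME_TO_LETTER and len(r) > 1 and rl[0] == ql[0]:
            rs[j] = (r[0], rsep)
            rs.insert(j + 1, (r[1:], False))
            continue
        if rl in GREEK_NAME_TO_LETTER and len(q) > 1 and ql[0] == rl[0]:
            qs[i] = (q[0], qsep)
            qs.insert(i + 1, (q[1:], False))
            continue
        return None
    if i < len(qs) or j < len(rs):
        return None
    return mismatch, caps


def compare_strings(query: str, ref: str) -> MatchFeatures:
    """Compare the original query string with a matched term's text.

    Both strings are NFC-normalized (micro sign folded) but *not*
    canonicalized: case and separators are exactly what the features
    measure.  When direct alignment fails and the query carries a
    trailing plural marker, the comparison is retried on the
    de-pluralized query with ``plural_dropped`` set.
    """
    qn, rn = _prepare(query), _prepare(ref)
    if qn == rn:
        return MatchFeatures(
            query=query, ref=ref, exact=True,
            space_dash_mismatch=0, cap_profile=(), plural_dropped=False,
        )
    rsegs = _segments(rn)
    aligned = _align(_segments(qn), rsegs)
    plural = False
    if aligned is None:
        stripped = _strip_plural_text(qn)
        if stripped is not None:
            retry = _align(_segments(stripped), rsegs)
            if retry is not None:
                aligned = retry
                plural = True
    if aligned is None:
        return MatchFeatures(
            query=query, ref=ref, exact=False,
            space_dash_mismatch=0, cap_profile=(), plural_dropped=False,
            aligned=False,
        )
    mismatch, caps = aligned
    return MatchFeatures(
        query=query, ref=ref, exact=False,
        space_dash_mismatch=mismatch, cap_profile=tuple(caps),
        plural_dropped=plural,
    )


def _strip_plural_text(text: str) -> str | None:
    if text.endswith("ies") and len(text) > 3:
        return text[:-3] + "y"
    if (text.endswith("s") or text.endswith("S")) and not text.lower().endswith("ss"):
        stem = text[:-1]
        if len(stem.strip()) >= 3:
            return stem
    return None


_STATUS_RANK = {"standard_name": 0, "curated": 1, "synonym": 2, "former_name": 3}


def score_match(
    features: MatchFeatures,
    status: str,
    config: ScoringConfig = DEFAULT_SCORING,
) -> float:
    """Score a candidate match in [0, 1].

    ``score = similarity * status_multiplier`` where similarity is the
    product of per-feature penalties (1.0 for an exact string match) and
    the status multiplier is 1.0 for a standard name.  Hence an exact
    match of a standard name scores exactly 1.0, and every additional
    feature mismatch or status downgrade strictly lowers the score.
    """
    status_value = getattr(status, "value", status)
    pen = config.penalties
    sim = 1.0
    if not features.exact:
        sim *= pen["space_dash_mismatch"] ** features.space_dash_mismatch
        for cap in features.cap_profile:
            if cap == CAP_SAME:
                continue
            if cap == CAP_QUERY_UPPER_REF_LOWER:
                sim *= pen["cap_query_upper_ref_lower"]
            elif cap == CAP_QUERY_LOWER_REF_UPPER:
                sim *= pen["cap_query_lower_ref_upper"]
            else:
                sim *= pen["cap_mixed"]
        if features.plural_dropped:
            sim *= pen["plural_dropped"]
        if not features.aligned:
            sim *= pen["unaligned"]
    score = sim * config.status_multipliers[status_value]
    return min(1.0, max(0.0, score))


# ---------------------------------------------------------------------------
# grounding pipeline
# ---------------------------------------------------------------------------


def _tie_break_key(match: ScoredMatch) -> tuple:
    term = match.term
    status_value = getattr(term.status, "value", term.status)
    return (
        -match.score,
        _STATUS_RANK.get(status_value, 99),
        match.features.mismatch_count(),
        term.source,
        term.namespace,
        term.identifier,
        term.text,
    )


def ground(
    index: "GroundingIndex",
    text: str,
    context: str | None = None,
    organisms: Sequence[str] | None = None,
    models: "DisambRegistry | None" = None,
    config: ScoringConfig = DEFAULT_SCORING,
) -> list[ScoredMatch]:
    """Ground an entity string against the index.

    Pipeline: variant generation -> exact canonical lookup (including
    de-pluralized variants) -> per-candidate scoring -> per-entity
    deduplication keeping the best-scoring match -> optional
    context-based score adjustment (when ``context`` is given and a
    disambiguation model exists for the canonicalized input) -> optional
    species-priority reranking of tied matches -> deterministic
    score-descending order.
    """
    if not text or not text.strip():
        raise ValueError("cannot ground an empty entity string")

    variants = generate_variants(text)
    keys = list(variants)
    for v in variants:
        stem = depluralize(v)
        if stem is not None and stem not in keys:
            keys.append(stem)

    best: dict[tuple[str, str], ScoredMatch] = {}
    for term, variant in lookup(index, keys):
        features = compare_strings(text, term.text)
        score = score_match(features, term.status, config)
        candidate = ScoredMatch(
            term=term, score=score, features=features, variant_used=variant
        )
        key = candidate.entity
        incumbent = best.get(key)
        if incumbent is None or _tie_break_key(candidate) < _tie_break_key(incumbent):
            best[key] = candidate

    matches = sorted(best.values(), key=_tie_break_key)

    if context is not None and matches:
        canonical = canonicalize(text)
        model = models.get(canonical) if models is not None else None
        if model is None:
            logger.debug(
                "no disambiguation model for %r; context ignored", canonical
            )
        else:
            from .disambiguation import apply_to_matches, disambiguate

            probabilities = disambiguate(model, context)
            matches = apply_to_matches(matches, probabilities)

    if organisms:
        from .species import SpeciesPriority, rerank_by_species

        priority = (
            organisms
            if isinstance(organisms, SpeciesPriority)
            else SpeciesPriority(tuple(str(o) for o in organisms))
        )
        matches = rerank_by_species(matches, priority)

    return matches


@dataclass
class Grounder:
    """A grounding engine: an index plus optional disambiguation models.

    Convenience front door used by the CLI and the web service; the
    functional pipeline is :func:`ground`.
    """

    index: "GroundingIndex"
    models: "DisambRegistry | None" = None
    config: ScoringConfig = field(default=DEFAULT_SCORING)

    def ground(
        self,
        text: str,
        context: str | None = None,
        organisms: Sequence[str] | None = None,
    ) -> list[ScoredMatch]:
        return ground(
            self.index,
            text,
            context=context,
            organisms=organisms,
            models=self.models,
            config=self.config,
        )


def scored_match_to_dict(match: ScoredMatch) -> dict:
    """JSON-ready representation shared by the CLI and the web service."""
    term = match.term
    status_value = getattr(term.status, "value", term.status)
    out = {
        "term": {
            "namespace": term.namespace,
            "id": term.identifier,
            "text": term.text,
            "status": status_value,
            "standard_name": term.standard_name,
            "organism": term.organism,
        },
        "score": match.score,
        "variant_used": match.variant_used,
    }
    if match.disamb_probability is not None:
        out["disamb_probability"] = match.disamb_probability
    return out
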