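"""Term data model, term-table and OBO I/O, and the grounding index.

A *term* is one lexicalization of one entity: a namespace + identifier
(e.g. HGNC:6840), the text of the name or synonym, the status of that
text (standard name, curated synonym, plain synonym, or former name),
the entity's standard name, a provenance source code, an optional
source namespace/identifier when the term was created by mapping from
another namespace, and an optional organism (taxonomy id) for genes and
proteins.

Term tables are serialized as 9-column UTF-8 TSV (gzip-transparent):

    namespace  id  text  status  canonical  standard_name  source
    source_ns:source_id  organism

with the last two columns optional (empty).  The grounding index is a
hash map from canonicalized text to the terms carrying that text, so
candidate lookup is constant-time on average regardless of lexicon
size.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from .stringmatch import canonicalize

logger = logging.getLogger(__name__)

__all__ = [
    "TermStatus",
    "Term",
    "GroundingIndex",
    "IndexConfig",
    "OboIngestConfig",
    "load_terms",
    "write_terms",
    "load_obo",
    "merge_gene_protein",
    "build_index",
]


class TermStatus(str, Enum):
    """Provenance/quality class of a lexicalization, best first."""

    STANDARD_NAME = "standard_name"
    CURATED = "curated"
    SYNONYM = "synonym"
    FORMER_NAME = "former_name"


@dataclass(frozen=True)
class Term:
    """One lexicalization of one entity."""

    namespace: str
    identifier: str
    text: str
    status: TermStatus
    standard_name: str
    source: str
    canonical: str = ""
    source_namespace: str | None = None
    source_identifier: str | None = None
    organism: str | None = None

    def __post_init__(self) -> None:
        for name in ("namespace", "identifier", "text", "standard_name", "source"):
            if not getattr(self, name):
                raise ValueError(f"Term field {name!r} must be non-empty")
        status = TermStatus(self.status)
        object.__setattr__(self, "status", status)
        expected = canonicalize(self.text)
        if not self.canonical:
            object.__setattr__(self, "canonical", expected)
        elif self.canonical != expected:
            raise ValueError(
                f"canonical {self.canonical!r} does not match "
                f"canonicalize({self.text!r}) == {expected!r}"
            )
        if (self.source_namespace is None) != (self.source_identifier is None):
            raise ValueError(
                "source_namespace and source_identifier must be set together"
            )

    @property
    def entity(self) -> tuple[str, str]:
        return (self.namespace, self.identifier)

    def dedup_key(self) -> tuple:
        return (self.namespace, self.identifier, self.text, self.status, self.organism)


# ---------------------------------------------------------------------------
# TSV term tables
# ---------------------------------------------------------------------------

_N_COLUMNS = 9


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def load_terms(path: str | Path) -> list[Term]:
    """Read a term table (9-column TSV, gzip-transparent, no header).

    Duplicated rows are preserved here; deduplication happens at index
    build.  Raises ``ValueError`` naming the line number for malformed
    rows and unknown statuses.
    """
    terms: list[Term] = []
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != _N_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_N_COLUMNS} tab-separated "
                    f"fields, got {len(fields)}"
                )
            (ns, ident, text, status, canonical, standard, source,
             mapped, organism) = fields
            try:
                status_value = TermStatus(status)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unknown status {status!r}"
                ) from None
            source_ns = source_id = None
            if mapped:
                if ":" not in mapped:
                    raise ValueError(
                        f"{path}:{lineno}: mapped-from field {mapped!r} is "
                        "not of the form namespace:identifier"
                    )
                source_ns, source_id = mapped.split(":", 1)
            try:
                terms.append(
                    Term(
                        namespace=ns,
                        identifier=ident,
                        text=text,
                        status=status_value,
                        canonical=canonical,
                        standard_name=standard,
                        source=source,
                        source_namespace=source_ns,
                        source_identifier=source_id,
                        organism=organism or None,
                    )
                )
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
    return terms


def write_terms(terms: Iterable[Term], path: str | Path) -> None:
    """Write a term table readable back by :func:`load_terms`."""
    with _open_text(path, "w") as fh:
        for term in terms:
            mapped = (
                f"{term.source_namespace}:{term.source_identifier}"
                if term.source_namespace is not None
                else ""
            )
            row = (
                term.namespace,
                term.identifier,
                term.text,
                term.status.value,
                term.canonical,
                term.standard_name,
                term.source,
                mapped,
                term.organism or "",
            )
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# OBO ingestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OboIngestConfig:
    """How OBO stanzas map to terms.

    scope_status
        Synonym scope (EXACT, RELATED, ...) -> term status; scopes
        absent from the mapping are skipped.  The stanza name itself
        always becomes a standard_name term.
    keep_obsolete
        Obsolete stanzas become former_name terms when True, otherwise
        they are skipped entirely.
    namespace
        Override the namespace; by default it is taken from the id
        prefix (``GO:0006915`` -> ``GO``).
    """

    scope_status: Mapping[str, TermStatus] = field(
        default_factory=lambda: {"EXACT": TermStatus.SYNONYM}
    )
    keep_obsolete: bool = False
    namespace: str | None = None
    source: str | None = None


def load_obo(path: str | Path, config: OboIngestConfig | None = None) -> list[Term]:
    """Load terms from an OBO 1.4 flat file.

    One term per stanza name (status standard_name) plus one per synonym
    whose scope is selected by the config.  Stanzas without a name are
    skipped with a warning.
    """
    import obonet

    config = config or OboIngestConfig()
    graph = obonet.read_obo(str(path), ignore_obsolete=not config.keep_obsolete)
    terms: list[Term] = []
    for node, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            logger.warning("OBO stanza %s has no name; skipped", node)
            continue
        if ":" in node:
            prefix, ident = node.split(":", 1)
        else:
            prefix, ident = (config.namespace or "OBO"), node
        namespace = config.namespace or prefix
        source = config.source or namespace.lower()
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        if obsolete and not config.keep_obsolete:
            continue
        name_status = TermStatus.FORMER_NAME if obsolete else TermStatus.STANDARD_NAME
        terms.append(
            Term(
                namespace=namespace,
                identifier=ident,
                text=name,
                status=name_status,
                standard_name=name,
                source=source,
            )
        )
        for raw in data.get("synonym", []):
            parsed = _parse_obo_synonym(raw)
            if parsed is None:
                logger.warning("unparseable synonym in stanza %s: %r", node, raw)
                continue
            text, scope = parsed
            status = config.scope_status.get(scope)
            if status is None:
                continue
            if obsolete:
                status = TermStatus.FORMER_NAME
            try:
                terms.append(
                    Term(
                        namespace=namespace,
                        identifier=ident,
                        text=text,
                        status=status,
                        standard_name=name,
                        source=source,
                    )
                )
            except ValueError:
                logger.warning("invalid synonym text in stanza %s: %r", node, raw)
    return terms


def _parse_obo_synonym(raw: str) -> tuple[str, str] | None:
    """Parse an OBO synonym clause like ``"text" EXACT []``."""
    raw = raw.strip()
    if not raw.startswith('"'):
        return None
    end = raw.find('"', 1)
    while end != -1 and raw[end - 1] == "\\":
        end = raw.find('"', end + 1)
    if end == -1:
        return None
    text = raw[1:end].replace('\\"', '"')
    rest = raw[end + 1 :].strip()
    scope = rest.split()[0] if rest else "RELATED"
    if not scope.isupper():
        scope = "RELATED"
    return text, scope


# ---------------------------------------------------------------------------
# gene/protein merging
# ---------------------------------------------------------------------------


def merge_gene_protein(
    terms: Sequence[Term],
    mapping: Mapping[tuple[str, str], tuple[str, str]],
    enabled: bool = True,
) -> list[Term]:
    """Merge protein synonyms into their gene entries.

    ``mapping`` maps (protein namespace, protein id) -> (gene namespace,
    gene id).  Protein terms with a mapped gene are re-emitted under the
    gene's namespace/identifier with ``source_namespace`` /
    ``source_identifier`` recording the original; everything else passes
    through.  Gene/protein merging is on by default — scientific text
    rarely distinguishes a gene from its protein product — and can be
    disabled, in which case the input is returned unchanged.

    Raises ``ValueError`` when one protein maps to multiple genes
    (checked over the mapping as provided).
    """
    if not enabled or not mapping:
        return list(terms)
    seen: dict[tuple[str, str], tuple[str, str]] = {}
    conflicts = []
    for protein, gene in mapping.items():
        if protein in seen and seen[protein] != gene:
            conflicts.append((protein, seen[protein], gene))
        seen[protein] = gene
    if conflicts:
        raise ValueError(f"proteins mapped to multiple genes: {conflicts}")
    out: list[Term] = []
    for term in terms:
        target = mapping.get(term.entity)
        if target is None:
            out.append(term)
            continue
        gene_ns, gene_id = target
        out.append(
            replace(
                term,
                namespace=gene_ns,
                identifier=gene_id,
                source_namespace=term.namespace,
                source_identifier=term.identifier,
            )
        )
    return out


# ---------------------------------------------------------------------------
# grounding index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndexConfig:
    merge_gene_protein: bool = True


@dataclass
class GroundingIndex:
    """Hash map from canonical text to the terms carrying that text."""

    entries: dict[str, list[Term]]
    config: IndexConfig = field(default_factory=IndexConfig)
    build_report: dict = field(default_factory=dict)

    def lookup(self, key: str) -> list[Term]:
        return self.entries.get(key, [])

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_terms(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def __iter__(self) -> Iterator[Term]:
        for terms in self.entries.values():
            yield from terms


def build_index(
    terms: Iterable[Term], config: IndexConfig | None = None
) -> GroundingIndex:
    """Build the canonical-text index.

    Duplicate (namespace, identifier, text, status, organism) tuples
    under one key are silently collapsed and counted in the build
    report, which also tallies terms per source and per status.
    """
    config = config or IndexConfig()
    entries: dict[str, list[Term]] = {}
    seen: set[tuple] = set()
    duplicates = 0
    by_source: Counter[str] = Counter()
    by_status: Counter[str] = Counter()
    for term in terms:
        key = term.dedup_key()
        if key in seen:
            duplicates += 1
            continue
        seen.add(key)
        entries.setdefault(term.canonical, []).append(term)
        by_source[term.source] += 1
        by_status[term.status.value] += 1
    report = {
        "n_terms": len(seen),
        "n_keys": len(entries),
        "duplicates_collapsed": duplicates,
        "by_source": dict(by_source),
        "by_status": dict(by_status),
    }
    return GroundingIndex(entries=entries, config=config, build_report=report)
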